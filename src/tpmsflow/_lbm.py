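"""D3Q19 lattice kernels (numba).

Internal module: the public solver lives in :mod:`tpmsflow.flow`.  The
scheme is a single-relaxation-time lattice-kinetic discretization with
regularized collision: before relaxing, the non-equilibrium part of each
population is projected onto its second-order (viscous stress) moment,
which removes the spurious higher-order modes that destabilize plain BGK
at relaxation times close to 1/2.  In the low-Mach limit the scheme
recovers incompressible laminar Navier-Stokes flow.

Boundaries: walls (any inactive neighbour) use halfway bounce-back; port
cells sit on the grid boundary and their populations arriving from
outside are set by the anti-bounce-back pressure rule, which fixes the
reservoir density half a link beyond the cap.

Implementation notes: populations are stored structure-of-arrays,
``f[i, x, y, z]``, so the pull gather walks contiguous z-lines; a
per-cell type code (inactive / bulk / wall-adjacent / port) lets interior
cells skip all boundary logic; streaming and collision are fused in one
pass, so the stored state is always post-collision and bounce-back reads
the cell's own opposite population from the previous step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# rest, then +-x, +-y, +-z, then the 12 edge diagonals; opposites adjacent
CX = np.array([0, 1, -1, 0, 0, 0, 0, 1, -1, 1, -1, 1, -1, 1, -1, 0, 0, 0, 0], np.int64)
CY = np.array([0, 0, 0, 1, -1, 0, 0, 1, -1, -1, 1, 0, 0, 0, 0, 1, -1, 1, -1], np.int64)
CZ = np.array([0, 0, 0, 0, 0, 1, -1, 0, 0, 0, 0, 1, -1, -1, 1, 1, -1, -1, 1], np.int64)
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)
OPP = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16, 15, 18, 17], np.int64)

CS2 = 1.0 / 3.0

# cell type codes
INACTIVE, BULK, BOUNDARY, PORT = 0, 1, 2, 3


def cell_types(active: np.ndarray, is_port: np.ndarray) -> np.ndarray:
    """Classify cells: ports and wall-adjacent cells need boundary logic,
    interior (bulk) cells pull from 18 active neighbours unconditionally."""
    bulk = active.copy()
    for i in range(1, 19):
        c = (int(CX[i]), int(CY[i]), int(CZ[i]))
        # nbr[x] = active[x + c], with out-of-grid neighbours inactive
        nbr = np.roll(active, tuple(-v for v in c), axis=(0, 1, 2))
        for ax, v in enumerate(c):
            if v > 0:
                idx = [slice(None)] * 3
                idx[ax] = slice(-v, None)
                nbr[tuple(idx)] = False
            elif v < 0:
                idx = [slice(None)] * 3
                idx[ax] = slice(None, -v)
                nbr[tuple(idx)] = False
        bulk &= nbr
    out = np.zeros(active.shape, dtype=np.int8)
    out[active] = BOUNDARY
    out[bulk] = BULK
    out[is_port] = PORT
    return np.ascontiguousarray(out)


@njit(cache=True, fastmath=True)
def init_equilibrium(celltype, rho0):
    """Zero-velocity equilibrium at the given density field."""
    nx, ny, nz = celltype.shape
    f = np.zeros((19, nx, ny, nz))
    for i in range(19):
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if celltype[x, y, z] != INACTIVE:
                        f[i, x, y, z] = W[i] * rho0[x, y, z]
    return f


@njit(cache=True, fastmath=True)
def init_equilibrium_u(celltype, rho0, u0):
    """Equilibrium at a given density and velocity field (warm start)."""
    nx, ny, nz = celltype.shape
    f = np.zeros((19, nx, ny, nz))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if celltype[x, y, z] == INACTIVE:
                    continue
                r = rho0[x, y, z]
                ux = u0[x, y, z, 0]
                uy = u0[x, y, z, 1]
                uz = u0[x, y, z, 2]
                usq = ux * ux + uy * uy + uz * uz
                for i in range(19):
                    cu = CX[i] * ux + CY[i] * uy + CZ[i] * uz
                    f[i, x, y, z] = W[i] * r * (
                        1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq
                    )
    return f


@njit(cache=True, fastmath=True)
def step(fsrc, fdst, celltype, rho_bc, omega):
    """One fused stream + regularized-collide update (pull scheme).

    The collision is fully unrolled: moments, equilibria and the stress
    projection are written out per direction so everything stays in
    registers (the code mirrors the generic formulation in the module
    docstring term by term)."""
    nx, ny, nz = celltype.shape
    W0 = 1.0 / 3.0
    W1 = 1.0 / 18.0
    W2 = 1.0 / 36.0
    ONETHIRD = 1.0 / 3.0
    fac = (1.0 - omega) * 4.5
    FW0 = fac * W0
    FW1 = fac * W1
    FW2 = fac * W2
    buf = np.empty(19)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                ct = celltype[x, y, z]
                if ct == INACTIVE:
                    continue

                if ct == BULK:
                    f0 = fsrc[0, x, y, z]
                    f1 = fsrc[1, x - 1, y, z]
                    f2 = fsrc[2, x + 1, y, z]
                    f3 = fsrc[3, x, y - 1, z]
                    f4 = fsrc[4, x, y + 1, z]
                    f5 = fsrc[5, x, y, z - 1]
                    f6 = fsrc[6, x, y, z + 1]
                    f7 = fsrc[7, x - 1, y - 1, z]
                    f8 = fsrc[8, x + 1, y + 1, z]
                    f9 = fsrc[9, x - 1, y + 1, z]
                    f10 = fsrc[10, x + 1, y - 1, z]
                    f11 = fsrc[11, x - 1, y, z - 1]
                    f12 = fsrc[12, x + 1, y, z + 1]
                    f13 = fsrc[13, x - 1, y, z + 1]
                    f14 = fsrc[14, x + 1, y, z - 1]
                    f15 = fsrc[15, x, y - 1, z - 1]
                    f16 = fsrc[16, x, y + 1, z + 1]
                    f17 = fsrc[17, x, y - 1, z + 1]
                    f18 = fsrc[18, x, y + 1, z - 1]
                else:
                    # boundary velocity for the anti-bounce-back rule
                    bx = 0.0
                    by = 0.0
                    bz = 0.0
                    bsq = 0.0
                    if ct == PORT:
                        br = 0.0
                        for i in range(19):
                            fi = fsrc[i, x, y, z]
                            br += fi
                            bx += CX[i] * fi
                            by += CY[i] * fi
                            bz += CZ[i] * fi
                        binv = 1.0 / br
                        bx *= binv
                        by *= binv
                        bz *= binv
                        bsq = bx * bx + by * by + bz * bz
                    for i in range(19):
                        sx = x - CX[i]
                        sy = y - CY[i]
                        sz = z - CZ[i]
                        inside = 0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz
                        if inside and celltype[sx, sy, sz] != INACTIVE:
                            buf[i] = fsrc[i, sx, sy, sz]
                        elif ct == PORT and not inside:
                            cu = CX[i] * bx + CY[i] * by + CZ[i] * bz
                            buf[i] = -fsrc[OPP[i], x, y, z] + 2.0 * W[i] * rho_bc[
                                x, y, z
                            ] * (1.0 + 4.5 * cu * cu - 1.5 * bsq)
                        else:
                            buf[i] = fsrc[OPP[i], x, y, z]
                    f0 = buf[0]; f1 = buf[1]; f2 = buf[2]; f3 = buf[3]; f4 = buf[4]; f5 = buf[5]; f6 = buf[6]; f7 = buf[7]; f8 = buf[8]; f9 = buf[9]; f10 = buf[10]; f11 = buf[11]; f12 = buf[12]; f13 = buf[13]; f14 = buf[14]; f15 = buf[15]; f16 = buf[16]; f17 = buf[17]; f18 = buf[18]

                ux = (f1 + f7 + f9 + f11 + f13) - (f2 + f8 + f10 + f12 + f14)
                uy = (f3 + f7 + f10 + f15 + f17) - (f4 + f8 + f9 + f16 + f18)
                uz = (f5 + f11 + f14 + f15 + f18) - (f6 + f12 + f13 + f16 + f17)
                rho = f0 + f1 + f2 + f3 + f4 + f5 + f6 + f7 + f8 + f9 + f10 + f11 + f12 + f13 + f14 + f15 + f16 + f17 + f18
                inv = 1.0 / rho
                ux *= inv; uy *= inv; uz *= inv
                usq = ux * ux + uy * uy + uz * uz
                om15u = 1.0 - 1.5 * usq
                wr0 = W0 * rho; wr1 = W1 * rho; wr2 = W2 * rho
                e0 = wr0 * om15u
                n0 = f0 - e0
                c1 = ux
                e1 = wr1 * (om15u + c1 * (3.0 + 4.5 * c1))
                n1 = f1 - e1
                c2 = - ux
                e2 = wr1 * (om15u + c2 * (3.0 + 4.5 * c2))
                n2 = f2 - e2
                c3 = uy
                e3 = wr1 * (om15u + c3 * (3.0 + 4.5 * c3))
                n3 = f3 - e3
                c4 = - uy
                e4 = wr1 * (om15u + c4 * (3.0 + 4.5 * c4))
                n4 = f4 - e4
                c5 = uz
                e5 = wr1 * (om15u + c5 * (3.0 + 4.5 * c5))
                n5 = f5 - e5
                c6 = - uz
                e6 = wr1 * (om15u + c6 * (3.0 + 4.5 * c6))
                n6 = f6 - e6
                c7 = ux + uy
                e7 = wr2 * (om15u + c7 * (3.0 + 4.5 * c7))
                n7 = f7 - e7
                c8 = - ux - uy
                e8 = wr2 * (om15u + c8 * (3.0 + 4.5 * c8))
                n8 = f8 - e8
                c9 = ux - uy
                e9 = wr2 * (om15u + c9 * (3.0 + 4.5 * c9))
                n9 = f9 - e9
                c10 = - ux + uy
                e10 = wr2 * (om15u + c10 * (3.0 + 4.5 * c10))
                n10 = f10 - e10
                c11 = ux + uz
                e11 = wr2 * (om15u + c11 * (3.0 + 4.5 * c11))
                n11 = f11 - e11
                c12 = - ux - uz
                e12 = wr2 * (om15u + c12 * (3.0 + 4.5 * c12))
                n12 = f12 - e12
                c13 = ux - uz
                e13 = wr2 * (om15u + c13 * (3.0 + 4.5 * c13))
                n13 = f13 - e13
                c14 = - ux + uz
                e14 = wr2 * (om15u + c14 * (3.0 + 4.5 * c14))
                n14 = f14 - e14
                c15 = uy + uz
                e15 = wr2 * (om15u + c15 * (3.0 + 4.5 * c15))
                n15 = f15 - e15
                c16 = - uy - uz
                e16 = wr2 * (om15u + c16 * (3.0 + 4.5 * c16))
                n16 = f16 - e16
                c17 = uy - uz
                e17 = wr2 * (om15u + c17 * (3.0 + 4.5 * c17))
                n17 = f17 - e17
                c18 = - uy + uz
                e18 = wr2 * (om15u + c18 * (3.0 + 4.5 * c18))
                n18 = f18 - e18
                pxx = n1 + n2 + n7 + n8 + n9 + n10 + n11 + n12 + n13 + n14
                pyy = n3 + n4 + n7 + n8 + n9 + n10 + n15 + n16 + n17 + n18
                pzz = n5 + n6 + n11 + n12 + n13 + n14 + n15 + n16 + n17 + n18
                pxy = n7 +n8 -n9 -n10
                pxz = n11 +n12 -n13 -n14
                pyz = n15 +n16 -n17 -n18
                tr = (pxx + pyy + pzz) * ONETHIRD
                fdst[0, x, y, z] = e0 + FW0 * (0.0 - tr )
                fdst[1, x, y, z] = e1 + FW1 * (pxx - tr )
                fdst[2, x, y, z] = e2 + FW1 * (pxx - tr )
                fdst[3, x, y, z] = e3 + FW1 * (pyy - tr )
                fdst[4, x, y, z] = e4 + FW1 * (pyy - tr )
                fdst[5, x, y, z] = e5 + FW1 * (pzz - tr )
                fdst[6, x, y, z] = e6 + FW1 * (pzz - tr )
                fdst[7, x, y, z] = e7 + FW2 * (pxx + pyy - tr + 2.0 * pxy)
                fdst[8, x, y, z] = e8 + FW2 * (pxx + pyy - tr + 2.0 * pxy)
                fdst[9, x, y, z] = e9 + FW2 * (pxx + pyy - tr - 2.0 * pxy)
                fdst[10, x, y, z] = e10 + FW2 * (pxx + pyy - tr - 2.0 * pxy)
                fdst[11, x, y, z] = e11 + FW2 * (pxx + pzz - tr + 2.0 * pxz)
                fdst[12, x, y, z] = e12 + FW2 * (pxx + pzz - tr + 2.0 * pxz)
                fdst[13, x, y, z] = e13 + FW2 * (pxx + pzz - tr - 2.0 * pxz)
                fdst[14, x, y, z] = e14 + FW2 * (pxx + pzz - tr - 2.0 * pxz)
                fdst[15, x, y, z] = e15 + FW2 * (pyy + pzz - tr + 2.0 * pyz)
                fdst[16, x, y, z] = e16 + FW2 * (pyy + pzz - tr + 2.0 * pyz)
                fdst[17, x, y, z] = e17 + FW2 * (pyy + pzz - tr - 2.0 * pyz)
                fdst[18, x, y, z] = e18 + FW2 * (pyy + pzz - tr - 2.0 * pyz)



@njit(cache=True, fastmath=True)
def macroscopic(f, celltype):
    nx, ny, nz = celltype.shape
    rho = np.zeros((nx, ny, nz))
    u = np.zeros((nx, ny, nz, 3))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if celltype[x, y, z] == INACTIVE:
                    continue
                r = 0.0
                ux = 0.0
                uy = 0.0
                uz = 0.0
                for i in range(19):
                    fi = f[i, x, y, z]
                    r += fi
                    ux += CX[i] * fi
                    uy += CY[i] * fi
                    uz += CZ[i] * fi
                rho[x, y, z] = r
                inv = 1.0 / r
                u[x, y, z, 0] = ux * inv
                u[x, y, z, 1] = uy * inv
                u[x, y, z, 2] = uz * inv
    return rho, u
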
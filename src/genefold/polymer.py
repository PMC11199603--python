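"""Kinetic Monte Carlo of a TASEP-decorated lattice polymer.

Chromatin is a self-avoiding, semi-flexible chain on a face-centered cubic
(FCC) lattice with periodic boundaries: sites are integer triples (x, y, z)
with even coordinate sum, the 12 nearest neighbors are the permutations of
(+-1, +-1, 0), and one bond (50 nm) spans 2 kbp.  The Hamiltonian is

    H = kappa * sum_i (1 - cos theta_i) + E * sum_pairs f_ij s_i s_j

with bending rigidity ``kappa`` (kT), attraction ``E`` (kT) acting between
Pol II-bound monomers (s_i = 1) on nearest-neighbor sites (f_ij = 1), and
kT = 1.  When the interaction valency is limited, each bound monomer keeps a
list of at most ``valency`` partners; pairs persist while both members stay
bound and adjacent, and freed slots are refilled by scanning adjacent bound
monomers in random order.  Pol II dynamics along the gene(s) follow the
TASEP of :mod:`genefold.tasep`, one sweep per MCS, followed by N single-
monomer trial moves (kink/end relocations to vacant sites adjacent to the
chain neighbors) accepted by the Metropolis criterion.  TASEP moves are
never filtered by energy: Pol II-Pol II attraction does not impede
elongation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .tasep import TasepParams

__all__ = [
    "NEIGHBORS",
    "PolymerParams",
    "PolymerState",
    "PolymerTrajectory",
    "choose_box",
    "snake_path",
    "init_chain",
    "candidate_sites",
    "metropolis_accept",
    "total_energy",
    "check_invariants",
    "brute_force_pairs",
    "run",
]

#: the 12 FCC nearest-neighbor displacement vectors
NEIGHBORS = np.array(
    [[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0],
     [1, 0, 1], [1, 0, -1], [-1, 0, 1], [-1, 0, -1],
     [0, 1, 1], [0, 1, -1], [0, -1, 1], [0, -1, -1]],
    dtype=np.int64,
)

#: valency cap meaning "unlimited" (the FCC coordination number)
UNLIMITED = 12


def _build_tables():
    """Neighbor lookup table and shared-neighbor table keyed by the
    (min-image) displacement between the two chain neighbors of a monomer."""
    lut = np.zeros((5, 5, 5), dtype=np.bool_)
    for v in NEIGHBORS:
        lut[v[0] + 2, v[1] + 2, v[2] + 2] = True
    shared_cnt = np.zeros(125, dtype=np.int32)
    shared_off = np.zeros((125, 12, 3), dtype=np.int64)
    for d0 in range(-2, 3):
        for d1 in range(-2, 3):
            for d2 in range(-2, 3):
                idx = (d0 + 2) * 25 + (d1 + 2) * 5 + (d2 + 2)
                k = 0
                for v in NEIGHBORS:
                    w = (v[0] - d0, v[1] - d1, v[2] - d2)
                    if max(abs(w[0]), abs(w[1]), abs(w[2])) <= 2 and \
                            lut[w[0] + 2, w[1] + 2, w[2] + 2]:
                        shared_off[idx, k] = v
                        k += 1
                shared_cnt[idx] = k
    return lut, shared_cnt, shared_off


NB_LUT, SHARED_CNT, SHARED_OFF = _build_tables()


def choose_box(n_total: int, fill: float = 0.5) -> tuple[int, int, int]:
    """Smallest even cubic box whose FCC site count puts the chain at
    approximately the requested fill fraction (sites = L^3 / 2)."""
    if not 0 < fill <= 1:
        raise ValueError("fill fraction must be in (0, 1]")
    L = 2
    while L**3 / 2 * fill < n_total:
        L += 2
    return (L, L, L)


def snake_path(dims: tuple[int, int, int]) -> np.ndarray:
    """Hamiltonian boustrophedon path over every FCC site of the box.

    Planes are traversed in order of z; within each plane, strips of two y
    rows are zigzagged along x (direction alternating with plane parity) so
    consecutive sites are always lattice neighbors (wrapping across the
    periodic boundary).  The path is planar-layered, hence unknotted, and
    provides self-avoiding initial conformations: the first N sites seed a
    chain of N monomers.
    """
    Lx, Ly, Lz = dims
    if any(d % 2 or d < 4 for d in dims):
        raise ValueError("box dimensions must be even and >= 4")
    path = np.empty((Lx * Ly * Lz // 2, 3), dtype=np.int64)
    k = 0
    for z in range(Lz):
        xs = range(Lx) if z % 2 == 0 else range(Lx - 1, -1, -1)
        for b in range(Ly // 2):
            for x in xs:
                path[k, 0] = x
                path[k, 1] = 2 * b + ((x + z) % 2)
                path[k, 2] = z
                k += 1
    return path


@dataclass
class PolymerParams:
    """Geometry and energetics of the decorated chain.

    ``valency=0`` means unlimited (capped only by the 12 lattice neighbors).
    ``gene_spans`` are (first monomer index, length) pairs; monomers outside
    every span are neutral crowding background.  ``monomer_bp``/``bond_nm``
    fix the coarse-graining (2 kbp and 50 nm per monomer).
    """

    n_total: int
    gene_spans: tuple[tuple[int, int], ...]
    box: tuple[int, int, int] | None = None
    kappa: float = 1.2
    E: float = -3.0
    valency: int = 0
    monomer_bp: int = 2_000
    bond_nm: float = 50.0
    fill: float = 0.5

    def __post_init__(self) -> None:
        if self.box is None:
            self.box = choose_box(self.n_total, self.fill)
        sites = self.box[0] * self.box[1] * self.box[2] // 2
        if self.n_total > sites:
            raise ValueError("box too small for the chain")
        for start, length in self.gene_spans:
            if start < 0 or start + length > self.n_total or length < 2:
                raise ValueError("gene span must lie within the chain")
        if not 0 <= self.valency <= UNLIMITED:
            raise ValueError("valency must be in [0, 12] (0 = unlimited)")

    @property
    def valency_cap(self) -> int:
        return UNLIMITED if self.valency == 0 else self.valency

    @property
    def fill_fraction(self) -> float:
        return self.n_total / (self.box[0] * self.box[1] * self.box[2] / 2)


@dataclass
class PolymerState:
    """Complete mutable simulation state (arrays shared with the kernels)."""

    pos: np.ndarray        # (N, 3) wrapped lattice coordinates
    upos: np.ndarray       # (N, 3) unwrapped coordinates
    lattice: np.ndarray    # (Lx, Ly, Lz) occupancy, monomer index + 1
    s: np.ndarray          # (N,) Pol II occupancy
    partners: np.ndarray   # (N, 12) partner indices, -1 empty
    pcount: np.ndarray     # (N,) partner counts
    dims: np.ndarray       # (3,)
    params: PolymerParams


def init_chain(params: PolymerParams) -> PolymerState:
    """Unknotted, self-avoiding initial conformation from the snake path."""
    dims = np.asarray(params.box, dtype=np.int64)
    path = snake_path(params.box)
    pos = path[: params.n_total].copy()
    lattice = np.zeros(params.box, dtype=np.int32)
    for i, (x, y, z) in enumerate(pos):
        if lattice[x, y, z] != 0:
            raise RuntimeError("initial path self-intersects")
        lattice[x, y, z] = i + 1
    return PolymerState(
        pos=pos, upos=pos.copy(),
        lattice=lattice,
        s=np.zeros(params.n_total, dtype=np.uint8),
        partners=np.full((params.n_total, UNLIMITED), -1, dtype=np.int32),
        pcount=np.zeros(params.n_total, dtype=np.int32),
        dims=dims, params=params,
    )


# -- numba kernels -----------------------------------------------------------

@njit(cache=True, inline="always")
def _minimg(d, L):  # pragma: no cover - jitted
    if d > L // 2:
        d -= L
    elif d < -(L // 2):
        d += L
    return d


@njit(cache=True, inline="always")
def _wrap1(x, L):  # pragma: no cover - jitted
    # x is a lattice coordinate plus a +-1/+-2 offset
    if x < 0:
        return x + L
    if x >= L:
        return x - L
    return x


@njit(cache=True, inline="always")
def _adjacent(ax, ay, az, bx, by, bz, dims, lut):  # pragma: no cover
    dx = _minimg(bx - ax, dims[0])
    dy = _minimg(by - ay, dims[1])
    dz = _minimg(bz - az, dims[2])
    if dx < -2 or dx > 2 or dy < -2 or dy > 2 or dz < -2 or dz > 2:
        return False
    return lut[dx + 2, dy + 2, dz + 2]


@njit(cache=True, inline="always")
def _bond_cos(pos, i, j, k, dims):  # pragma: no cover
    """cos of the bending angle at j formed by monomers i-j-k."""
    ux = _minimg(pos[j, 0] - pos[i, 0], dims[0])
    uy = _minimg(pos[j, 1] - pos[i, 1], dims[1])
    uz = _minimg(pos[j, 2] - pos[i, 2], dims[2])
    vx = _minimg(pos[k, 0] - pos[j, 0], dims[0])
    vy = _minimg(pos[k, 1] - pos[j, 1], dims[1])
    vz = _minimg(pos[k, 2] - pos[j, 2], dims[2])
    return (ux * vx + uy * vy + uz * vz) / 2.0


@njit(cache=True)
def _is_partner(partners, pcount, m, q):  # pragma: no cover
    for k in range(pcount[m]):
        if partners[m, k] == q:
            return True
    return False


@njit(cache=True)
def _remove_one_sided(partners, pcount, a, b):  # pragma: no cover
    for k in range(pcount[a]):
        if partners[a, k] == b:
            partners[a, k] = partners[a, pcount[a] - 1]
            partners[a, pcount[a] - 1] = -1
            pcount[a] -= 1
            break


@njit(cache=True)
def _remove_pair(partners, pcount, m, q):  # pragma: no cover
    _remove_one_sided(partners, pcount, m, q)
    _remove_one_sided(partners, pcount, q, m)


@njit(cache=True)
def _add_pair(partners, pcount, m, q):  # pragma: no cover
    partners[m, pcount[m]] = q
    pcount[m] += 1
    partners[q, pcount[q]] = m
    pcount[q] += 1


@njit(cache=True)
def _fill_slots(pos, lattice, s, partners, pcount, dims, nb, valency, m):
    """Fill m's free slots with adjacent bound monomers, random scan order."""
    if s[m] == 0 or pcount[m] >= valency:
        return
    order = np.arange(12)
    for k in range(11, 0, -1):  # Fisher-Yates
        j = np.random.randint(0, k + 1)
        order[k], order[j] = order[j], order[k]
    for kk in range(12):
        if pcount[m] >= valency:
            break
        kk2 = order[kk]
        x = _wrap1(pos[m, 0] + nb[kk2, 0], dims[0])
        y = _wrap1(pos[m, 1] + nb[kk2, 1], dims[1])
        z = _wrap1(pos[m, 2] + nb[kk2, 2], dims[2])
        q = lattice[x, y, z] - 1
        if q >= 0 and q != m and s[q] == 1 and pcount[q] < valency and \
                not _is_partner(partners, pcount, m, q):
            _add_pair(partners, pcount, m, q)


@njit(cache=True)
def _drop_all_pairs(pos, lattice, s, partners, pcount, dims, nb, valency, m,
                    refill_partners):  # pragma: no cover
    while pcount[m] > 0:
        q = partners[m, 0]
        _remove_pair(partners, pcount, m, q)
        if refill_partners:
            _fill_slots(pos, lattice, s, partners, pcount, dims, nb, valency, q)


@njit(cache=True)
def _move_attempt(pos, upos, lattice, s, partners, pcount, dims,
                  kappa, E, valency, nb, lut, shared_cnt, shared_off):
    """One single-monomer trial move under the Metropolis criterion.

    Returns (status, dH): status 0 = null proposal, 1 = rejected,
    2 = accepted.  For accepted moves dH is exactly the change of the global
    Hamiltonian (bending + pair energy over the interaction lists).
    """
    n_total = pos.shape[0]
    m = np.random.randint(0, n_total)
    ox, oy, oz = pos[m, 0], pos[m, 1], pos[m, 2]
    # geometric candidate set: depends only on the fixed chain neighbors,
    # hence symmetric between forward and reverse proposals
    if m == 0 or m == n_total - 1:
        a = m + 1 if m == 0 else m - 1
        k = np.random.randint(0, 12)
        cx = _wrap1(pos[a, 0] + nb[k, 0], dims[0])
        cy = _wrap1(pos[a, 1] + nb[k, 1], dims[1])
        cz = _wrap1(pos[a, 2] + nb[k, 2], dims[2])
    else:
        d0 = _minimg(pos[m + 1, 0] - pos[m - 1, 0], dims[0])
        d1 = _minimg(pos[m + 1, 1] - pos[m - 1, 1], dims[1])
        d2 = _minimg(pos[m + 1, 2] - pos[m - 1, 2], dims[2])
        idx = (d0 + 2) * 25 + (d1 + 2) * 5 + (d2 + 2)
        cnt = shared_cnt[idx]
        if cnt == 0:
            return 0, 0.0
        k = np.random.randint(0, cnt)
        cx = _wrap1(pos[m - 1, 0] + shared_off[idx, k, 0], dims[0])
        cy = _wrap1(pos[m - 1, 1] + shared_off[idx, k, 1], dims[1])
        cz = _wrap1(pos[m - 1, 2] + shared_off[idx, k, 2], dims[2])
    if lattice[cx, cy, cz] != 0:
        return 0, 0.0  # occupied target (or the current site itself)

    # bending energy difference, only angles touching m change; bond vectors
    # are short, so per-component min-image differences are exact
    dH = 0.0
    if m > 0 and m < n_total - 1:
        u1x = _minimg(ox - pos[m - 1, 0], dims[0])
        u1y = _minimg(oy - pos[m - 1, 1], dims[1])
        u1z = _minimg(oz - pos[m - 1, 2], dims[2])
        u2x = _minimg(pos[m + 1, 0] - ox, dims[0])
        u2y = _minimg(pos[m + 1, 1] - oy, dims[1])
        u2z = _minimg(pos[m + 1, 2] - oz, dims[2])
        v1x = _minimg(cx - pos[m - 1, 0], dims[0])
        v1y = _minimg(cy - pos[m - 1, 1], dims[1])
        v1z = _minimg(cz - pos[m - 1, 2], dims[2])
        v2x = _minimg(pos[m + 1, 0] - cx, dims[0])
        v2y = _minimg(pos[m + 1, 1] - cy, dims[1])
        v2z = _minimg(pos[m + 1, 2] - cz, dims[2])
        # angle at m: kappa (1 - u1.u2 / 2)
        dH += 0.5 * kappa * ((u1x * u2x + u1y * u2y + u1z * u2z)
                             - (v1x * v2x + v1y * v2y + v1z * v2z))
        if m >= 2:
            wx = _minimg(pos[m - 1, 0] - pos[m - 2, 0], dims[0])
            wy = _minimg(pos[m - 1, 1] - pos[m - 2, 1], dims[1])
            wz = _minimg(pos[m - 1, 2] - pos[m - 2, 2], dims[2])
            dH += 0.5 * kappa * ((wx * u1x + wy * u1y + wz * u1z)
                                 - (wx * v1x + wy * v1y + wz * v1z))
        if m <= n_total - 3:
            xx = _minimg(pos[m + 2, 0] - pos[m + 1, 0], dims[0])
            xy = _minimg(pos[m + 2, 1] - pos[m + 1, 1], dims[1])
            xz = _minimg(pos[m + 2, 2] - pos[m + 1, 2], dims[2])
            dH += 0.5 * kappa * ((u2x * xx + u2y * xy + u2z * xz)
                                 - (v2x * xx + v2y * xy + v2z * xz))
    elif m == 0:
        # only the angle at monomer 1 changes
        u1x = _minimg(pos[1, 0] - ox, dims[0])
        u1y = _minimg(pos[1, 1] - oy, dims[1])
        u1z = _minimg(pos[1, 2] - oz, dims[2])
        v1x = _minimg(pos[1, 0] - cx, dims[0])
        v1y = _minimg(pos[1, 1] - cy, dims[1])
        v1z = _minimg(pos[1, 2] - cz, dims[2])
        if n_total >= 3:
            xx = _minimg(pos[2, 0] - pos[1, 0], dims[0])
            xy = _minimg(pos[2, 1] - pos[1, 1], dims[1])
            xz = _minimg(pos[2, 2] - pos[1, 2], dims[2])
            dH += 0.5 * kappa * ((u1x * xx + u1y * xy + u1z * xz)
                                 - (v1x * xx + v1y * xy + v1z * xz))
    else:
        u2x = _minimg(ox - pos[m - 1, 0], dims[0])
        u2y = _minimg(oy - pos[m - 1, 1], dims[1])
        u2z = _minimg(oz - pos[m - 1, 2], dims[2])
        v2x = _minimg(cx - pos[m - 1, 0], dims[0])
        v2y = _minimg(cy - pos[m - 1, 1], dims[1])
        v2z = _minimg(cz - pos[m - 1, 2], dims[2])
        if n_total >= 3:
            wx = _minimg(pos[m - 1, 0] - pos[m - 2, 0], dims[0])
            wy = _minimg(pos[m - 1, 1] - pos[m - 2, 1], dims[1])
            wz = _minimg(pos[m - 1, 2] - pos[m - 2, 2], dims[2])
            dH += 0.5 * kappa * ((wx * u2x + wy * u2y + wz * u2z)
                                 - (wx * v2x + wy * v2y + wz * v2z))

    # interaction energy difference: m's list re-resolved at the new site
    surviving = 0
    eligible = 0
    if s[m] == 1 and E != 0.0:
        for k in range(pcount[m]):
            p = partners[m, k]
            if _adjacent(cx, cy, cz, pos[p, 0], pos[p, 1], pos[p, 2], dims, lut):
                surviving += 1
        for k in range(12):
            x = _wrap1(cx + nb[k, 0], dims[0])
            y = _wrap1(cy + nb[k, 1], dims[1])
            z = _wrap1(cz + nb[k, 2], dims[2])
            q = lattice[x, y, z] - 1
            if q >= 0 and q != m and s[q] == 1 and pcount[q] < valency and \
                    not _is_partner(partners, pcount, m, q):
                eligible += 1
        new_pairs = min(valency, surviving + eligible)
        dH += E * (new_pairs - pcount[m])

    if dH > 0.0 and np.random.random() >= np.exp(-dH):
        return 1, dH

    # apply: lattice, wrapped and unwrapped coordinates
    lattice[ox, oy, oz] = 0
    lattice[cx, cy, cz] = m + 1
    upos[m, 0] += _minimg(cx - ox, dims[0])
    upos[m, 1] += _minimg(cy - oy, dims[1])
    upos[m, 2] += _minimg(cz - oz, dims[2])
    pos[m, 0], pos[m, 1], pos[m, 2] = cx, cy, cz
    if s[m] == 1:
        for k in range(pcount[m] - 1, -1, -1):
            p = partners[m, k]
            if not _adjacent(cx, cy, cz, pos[p, 0], pos[p, 1], pos[p, 2],
                             dims, lut):
                _remove_pair(partners, pcount, m, p)
        _fill_slots(pos, lattice, s, partners, pcount, dims, nb, valency, m)
    return 2, dH


@njit(cache=True)
def _tasep_sweep(pos, lattice, s, partners, pcount, dims, nb, valency,
                 gene_starts, gene_lens, prom_on, episodes, tags,
                 pa, pb, pg, pg0, pon, poff, bursting, maintain):
    """One TASEP MCS for every gene span, updating interaction lists."""
    for g in range(gene_starts.shape[0]):
        g0 = gene_starts[g]
        n = gene_lens[g]
        if prom_on[g] == 1 and s[g0] == 0 and np.random.random() < pa:
            s[g0] = 1
            tags[g0] = episodes[g]
            if maintain:
                _fill_slots(pos, lattice, s, partners, pcount, dims, nb,
                            valency, g0)
        last = g0 + n - 1
        if s[last] == 1 and np.random.random() < pb:
            s[last] = 0  # cleared first so freed partners cannot re-pair with it
            tags[last] = -1
            if maintain:
                _drop_all_pairs(pos, lattice, s, partners, pcount, dims, nb,
                                valency, last, True)
        for _ in range(n - 1):
            i = g0 + np.random.randint(0, n - 1)
            p = pg0 if i == g0 else pg
            if s[i] == 1 and s[i + 1] == 0 and np.random.random() < p:
                s[i] = 0
                if maintain:
                    _drop_all_pairs(pos, lattice, s, partners, pcount, dims,
                                    nb, valency, i, True)
                s[i + 1] = 1
                tags[i + 1] = tags[i]
                tags[i] = -1
                if maintain:
                    _fill_slots(pos, lattice, s, partners, pcount, dims, nb,
                                valency, i + 1)
        if bursting:
            if prom_on[g] == 1:
                if np.random.random() < poff:
                    prom_on[g] = 0
            else:
                if np.random.random() < pon:
                    prom_on[g] = 1
                    episodes[g] += 1


@njit(cache=True)
def _resolve_all(pos, lattice, s, partners, pcount, dims, nb, valency):
    """Rebuild every interaction list from scratch (random monomer order)."""
    n_total = pos.shape[0]
    partners[:, :] = -1
    pcount[:] = 0
    order = np.arange(n_total)
    for k in range(n_total - 1, 0, -1):
        j = np.random.randint(0, k + 1)
        order[k], order[j] = order[j], order[k]
    for k in range(n_total):
        _fill_slots(pos, lattice, s, partners, pcount, dims, nb, valency,
                    order[k])


@njit(cache=True)
def _run_kernel(pos, upos, lattice, s, partners, pcount, dims,
                kappa, E, valency, nb, lut, shared_cnt, shared_off,
                gene_starts, gene_lens, pa, pb, pg, pg0, pon, poff, bursting,
                steps, burn, snap_every, rec_lo, rec_hi, seed, tasep_pre,
                init_density, reshuffle_every):
    np.random.seed(seed)
    n_total = pos.shape[0]
    n_spans = gene_starts.shape[0]
    prom_on = np.ones(n_spans, dtype=np.uint8)
    episodes = np.zeros(n_spans, dtype=np.int64)
    tags = np.full(n_total, -1, dtype=np.int64)

    if init_density > 0.0:
        for g in range(n_spans):
            for i in range(gene_starts[g], gene_starts[g] + gene_lens[g]):
                if np.random.random() < init_density:
                    s[i] = 1
                    tags[i] = 0
    for _ in range(tasep_pre):
        _tasep_sweep(pos, lattice, s, partners, pcount, dims, nb, valency,
                     gene_starts, gene_lens, prom_on, episodes, tags,
                     pa, pb, pg, pg0, pon, poff, bursting, False)
    _resolve_all(pos, lattice, s, partners, pcount, dims, nb, valency)

    n_frames = (steps - burn) // snap_every if snap_every > 0 else 0
    rec = rec_hi - rec_lo
    pos_series = np.zeros((n_frames, rec, 3), dtype=np.int32)
    s_series = np.zeros((n_frames, rec), dtype=np.uint8)
    prom_series = np.zeros((n_frames, n_spans), dtype=np.uint8)
    train_series = np.zeros((n_frames, n_spans), dtype=np.int32)
    accepted = 0
    frame = 0
    for t in range(steps):
        _tasep_sweep(pos, lattice, s, partners, pcount, dims, nb, valency,
                     gene_starts, gene_lens, prom_on, episodes, tags,
                     pa, pb, pg, pg0, pon, poff, bursting, True)
        for _ in range(n_total):
            status, _dh = _move_attempt(pos, upos, lattice, s, partners,
                                        pcount, dims, kappa, E, valency, nb,
                                        lut, shared_cnt, shared_off)
            if status == 2:
                accepted += 1
        if reshuffle_every > 0 and valency < 12 and \
                (t + 1) % reshuffle_every == 0:
            # at unlimited valency the incremental lists already equal the
            # full adjacent-bound pair set; re-resolution would be a no-op
            _resolve_all(pos, lattice, s, partners, pcount, dims, nb, valency)
        if t >= burn and snap_every > 0 and (t - burn) % snap_every == 0 \
                and frame < n_frames:
            pos_series[frame] = upos[rec_lo:rec_hi].astype(np.int32)
            s_series[frame] = s[rec_lo:rec_hi]
            prom_series[frame] = prom_on
            for g in range(n_spans):
                g0 = gene_starts[g]
                n = gene_lens[g]
                cnt = 0
                for i in range(g0, g0 + n):
                    if s[i] == 1:
                        fresh = True
                        for j in range(g0, i):
                            if s[j] == 1 and tags[j] == tags[i]:
                                fresh = False
                                break
                        if fresh:
                            cnt += 1
                train_series[frame, g] = cnt
            frame += 1
    return pos_series, s_series, prom_series, train_series, accepted


# -- python-facing API -------------------------------------------------------

def candidate_sites(state: PolymerState, m: int) -> np.ndarray:
    """Geometric candidate sites for relocating monomer m (occupied or not).

    Interior monomers may move to any site simultaneously adjacent to both
    chain neighbors; chain ends to any of the 12 neighbors of their single
    neighbor.  The set depends only on the neighbors' positions, making the
    proposal symmetric.
    """
    pos, dims = state.pos, state.dims
    n = pos.shape[0]
    if m == 0 or m == n - 1:
        a = pos[1] if m == 0 else pos[n - 2]
        return (a[None, :] + NEIGHBORS) % dims[None, :]
    d = np.array([_minimg(int(pos[m + 1, k] - pos[m - 1, k]), int(dims[k]))
                  for k in range(3)])
    idx = (d[0] + 2) * 25 + (d[1] + 2) * 5 + (d[2] + 2)
    offs = SHARED_OFF[idx, : SHARED_CNT[idx]]
    return (pos[m - 1][None, :] + offs) % dims[None, :]


def metropolis_accept(dH: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dH)) at kT = 1."""
    return dH <= 0 or rng.random() < np.exp(-dH)


def total_energy(state: PolymerState) -> float:
    """Global Hamiltonian: bending plus E per pair in the interaction lists."""
    pos, dims = state.pos, state.dims
    n = pos.shape[0]
    bend = 0.0
    for j in range(1, n - 1):
        bend += 1.0 - _bond_cos(pos, j - 1, j, j + 1, dims)
    n_pairs = int(state.pcount.sum()) // 2
    return state.params.kappa * bend + state.params.E * n_pairs


def brute_force_pairs(state: PolymerState) -> set[tuple[int, int]]:
    """All pairs of Pol II-bound monomers on adjacent lattice sites."""
    pos, dims = state.pos, state.dims
    bound = np.flatnonzero(state.s)
    pairs = set()
    for a_i, i in enumerate(bound):
        for j in bound[a_i + 1:]:
            if _adjacent(pos[i, 0], pos[i, 1], pos[i, 2],
                         pos[j, 0], pos[j, 1], pos[j, 2], state.dims, NB_LUT):
                pairs.add((int(i), int(j)))
    return pairs


def check_invariants(state: PolymerState) -> None:
    """Raise AssertionError on any violated structural invariant."""
    pos, dims = state.pos, state.dims
    n = pos.shape[0]
    # chain connectivity: consecutive monomers on nearest-neighbor sites
    for i in range(n - 1):
        assert _adjacent(pos[i, 0], pos[i, 1], pos[i, 2],
                         pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2],
                         dims, NB_LUT), f"bond {i}-{i + 1} broken"
    # excluded volume + lattice bookkeeping
    occupied = {}
    for i in range(n):
        key = tuple(int(c) for c in pos[i])
        assert key not in occupied, f"monomers {occupied[key]} and {i} overlap"
        occupied[key] = i
        assert (pos[i].sum()) % 2 == 0, f"monomer {i} off the FCC sublattice"
        assert state.lattice[key] == i + 1, f"lattice table stale at {key}"
    assert np.count_nonzero(state.lattice) == n
    # interaction lists: symmetric, adjacent, bound, within valency
    cap = state.params.valency_cap
    for i in range(n):
        assert state.pcount[i] <= cap, f"monomer {i} exceeds valency"
        plist = state.partners[i, : state.pcount[i]]
        assert len(set(plist.tolist())) == len(plist), f"duplicate partner at {i}"
        for q in plist:
            assert state.s[i] == 1 and state.s[q] == 1, "pair with unbound monomer"
            assert _adjacent(pos[i, 0], pos[i, 1], pos[i, 2],
                             pos[q, 0], pos[q, 1], pos[q, 2], dims, NB_LUT), \
                f"pair {i}-{q} not adjacent"
            qlist = state.partners[q, : state.pcount[q]]
            assert i in qlist, f"asymmetric pair {i}-{q}"


@dataclass
class PolymerTrajectory:
    """Snapshot stream of a coupled TASEP-polymer run."""

    params: PolymerParams
    tasep: TasepParams
    positions: np.ndarray      # (frames, rec, 3) unwrapped coordinates
    occupancy: np.ndarray      # (frames, rec) Pol II occupancy
    promoter: np.ndarray       # (frames, n_spans)
    trains: np.ndarray         # (frames, n_spans)
    record_lo: int
    record_hi: int
    snapshot_every: int
    accepted_moves: int
    final_state: PolymerState = field(repr=False, default=None)  # type: ignore


def run(params: PolymerParams, tasep_params: TasepParams, steps: int,
        burn_in: int = 0, snapshot_every: int = 1000, seed: int = 0,
        record_span: tuple[int, int] | None = None,
        tasep_preequil: int = 0,
        init_density: float | None = None,
        reshuffle_every: int = 0) -> PolymerTrajectory:
    """Simulate: per MCS one TASEP sweep then ``n_total`` polymer trial moves.

    ``tasep_preequil`` extra TASEP-only sweeps run first so the Pol II
    occupancy starts at its own steady state (the occupancy relaxation time,
    ~n/gamma, would otherwise dominate the burn-in at realistic rates);
    ``init_density`` seeds the gene occupancy with independent draws at the
    target density before those sweeps, which shortens the pre-equilibration
    needed at slow (real-time calibrated) TASEP clocks.  Snapshots of the
    ``record_span`` monomers (default: all) are taken every
    ``snapshot_every`` MCS after ``burn_in``.  Identical seeds give bitwise
    identical snapshot streams.

    ``reshuffle_every=0`` (default) keeps pairs persistent while valid: a
    pair breaks only when its members separate or lose Pol II, and freed
    slots are refilled on the owner's next event.  A positive value instead
    re-resolves every interaction list from scratch (random monomer order)
    at that MCS cadence, making the pairing stochastic.  Both rules leave
    unlimited-valency lists equal to the full adjacent-bound pair set.
    """
    if any(length != tasep_params.n for _, length in params.gene_spans):
        raise ValueError("tasep_params.n must match every gene span length")
    state = init_chain(params)
    lo, hi = record_span if record_span is not None else (0, params.n_total)
    if not 0 <= lo < hi <= params.n_total:
        raise ValueError("record span out of range")
    starts = np.array([a for a, _ in params.gene_spans], dtype=np.int64)
    lens = np.array([b for _, b in params.gene_spans], dtype=np.int64)
    pa, pb, pg, pg0, pon, poff = tasep_params.probabilities()
    out = _run_kernel(
        state.pos, state.upos, state.lattice, state.s, state.partners,
        state.pcount, state.dims, params.kappa, params.E, params.valency_cap,
        NEIGHBORS, NB_LUT, SHARED_CNT, SHARED_OFF, starts, lens,
        pa, pb, pg, pg0, pon, poff, tasep_params.bursting,
        steps, burn_in, snapshot_every, lo, hi, seed, tasep_preequil,
        -1.0 if init_density is None else float(init_density),
        reshuffle_every,
    )
    pos_series, s_series, prom_series, train_series, accepted = out
    return PolymerTrajectory(
        params=params, tasep=tasep_params, positions=pos_series,
        occupancy=s_series, promoter=prom_series, trains=train_series,
        record_lo=lo, record_hi=hi, snapshot_every=snapshot_every,
        accepted_moves=int(accepted), final_state=state,
    )
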
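"""Measurables from polymer trajectories.

Turns snapshot streams into the quantities the model predicts: simulated
contact maps and intra-gene contact enrichment (IC), radius of gyration,
mean-squared displacement with power-law (anomalous diffusion) fits, the
MCS-to-seconds calibration against imaging data, burst-conditioned structure
statistics and inter-gene contact analysis.

Two monomers are in contact when they occupy nearest-neighbor FCC sites --
the same proximity notion that defines the interaction term f_ij.  Lattice
coordinates are in units of the cubic embedding grid; one bond (two grid
units of squared length) spans ``bond_nm`` (50 nm), so one grid unit is
``bond_nm / sqrt(2)`` nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .matrix import ContactMatrix, ObsExpMatrix
from .polymer import PolymerTrajectory

__all__ = [
    "MsdFit",
    "sim_contact_map",
    "sim_obs_exp",
    "sim_ic",
    "radius_of_gyration",
    "rg_series",
    "msd",
    "fit_powerlaw",
    "calibrate_time",
    "burst_conditioned_stats",
    "inter_gene_analysis",
    "unwrap_chain",
]


@njit(cache=True)
def _contact_counts(pos_series, dims):  # pragma: no cover - jitted
    F, M, _ = pos_series.shape
    counts = np.zeros((M, M))
    for f in range(F):
        for i in range(M):
            xi = pos_series[f, i, 0]
            yi = pos_series[f, i, 1]
            zi = pos_series[f, i, 2]
            for j in range(i + 1, M):
                dx = (pos_series[f, j, 0] - xi) % dims[0]
                if dx > dims[0] // 2:
                    dx -= dims[0]
                if dx < -1 or dx > 1:
                    continue
                dy = (pos_series[f, j, 1] - yi) % dims[1]
                if dy > dims[1] // 2:
                    dy -= dims[1]
                if dy < -1 or dy > 1:
                    continue
                dz = (pos_series[f, j, 2] - zi) % dims[2]
                if dz > dims[2] // 2:
                    dz -= dims[2]
                if dz < -1 or dz > 1:
                    continue
                if dx * dx + dy * dy + dz * dz == 2:
                    counts[i, j] += 1.0
                    counts[j, i] += 1.0
    return counts


def sim_contact_map(traj: PolymerTrajectory, lo: int | None = None,
                    hi: int | None = None) -> ContactMatrix:
    """Snapshot-averaged contact counts for monomers [lo, hi).

    Monomer indices are absolute chain positions and must lie inside the
    recorded span.  Contacts are counted once per snapshot per adjacent pair
    (bonded neighbors are always in contact).
    """
    lo = traj.record_lo if lo is None else lo
    hi = traj.record_hi if hi is None else hi
    if not traj.record_lo <= lo < hi <= traj.record_hi:
        raise ValueError("requested region outside the recorded span")
    if traj.positions.shape[0] == 0:
        raise ValueError("empty trajectory")
    sub = traj.positions[:, lo - traj.record_lo: hi - traj.record_lo, :]
    dims = np.asarray(traj.params.box, dtype=np.int64)
    counts = _contact_counts(sub.astype(np.int64), dims)
    counts /= traj.positions.shape[0]
    return ContactMatrix(values=counts, resolution=traj.params.monomer_bp,
                         chrom="sim")


def _expected_excluding(counts: np.ndarray, exclude: np.ndarray) -> np.ndarray:
    """Per-diagonal mean of pixels not flagged in the boolean exclude matrix.

    Excluding the implanted signal block(s) makes the expected curve a pure
    background decay: on a scaled simulation the gene occupies a sizeable
    fraction of each diagonal and would otherwise contaminate its own null.
    """
    n = counts.shape[0]
    expected = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(counts, offset=d)
        keep = ~np.diagonal(exclude, offset=d)
        if keep.any():
            expected[d] = diag[keep].mean()
    return expected


def sim_obs_exp(cmap: ContactMatrix,
                exclude_spans: list[tuple[int, int]] = ()) -> ObsExpMatrix:
    """Observed/expected of a simulated map, with signal regions excluded
    from the expected estimate.

    ``exclude_spans`` are (lo, hi) index ranges (relative to the map) whose
    intra- and cross-span pairs are left out of the per-diagonal background.
    """
    n = cmap.n_bins
    exclude = np.zeros((n, n), dtype=bool)
    for a_lo, a_hi in exclude_spans:
        for b_lo, b_hi in exclude_spans:
            exclude[a_lo:a_hi, b_lo:b_hi] = True
    expected = _expected_excluding(cmap.values, exclude)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = cmap.values / expected[d]
    oe[~np.isfinite(oe)] = np.nan
    return ObsExpMatrix(values=oe, resolution=cmap.resolution, chrom=cmap.chrom)


def sim_ic(traj: PolymerTrajectory, gene_span: tuple[int, int],
           region: tuple[int, int] | None = None) -> float:
    """IC of a simulated gene: mean obs/exp over intra-gene monomer pairs.

    The map is computed over ``region`` (default: the whole recorded span),
    the distance decay over background pairs (gene excluded), and the IC as
    the mean obs/exp over gene pairs i<j.
    """
    g0, glen = gene_span
    lo, hi = region if region is not None else (traj.record_lo, traj.record_hi)
    cmap = sim_contact_map(traj, lo, hi)
    a, b = g0 - lo, g0 - lo + glen
    oe = sim_obs_exp(cmap, exclude_spans=[(a, b)])
    block = oe.values[a:b, a:b]
    iu = np.triu_indices(glen, k=1)
    vals = block[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def radius_of_gyration(positions: np.ndarray, bond_nm: float = 50.0) -> float:
    """RG = sqrt(mean |r_i - r_mean|^2) in nm, positions unwrapped."""
    r = np.asarray(positions, dtype=float)
    rm = r.mean(axis=0)
    rg_lat = np.sqrt(((r - rm) ** 2).sum(axis=1).mean())
    return rg_lat * bond_nm / np.sqrt(2.0)


def rg_series(traj: PolymerTrajectory, span: tuple[int, int]) -> np.ndarray:
    """Per-snapshot RG (nm) of the monomers in the absolute span [lo, lo+len).

    Positions are re-unwrapped along the chain within each snapshot: the
    stored per-monomer coordinates are only continuous in time (for MSD),
    not across monomers once wrap counts differ.
    """
    g0, glen = span
    a = g0 - traj.record_lo
    dims = np.asarray(traj.params.box, dtype=np.int64)
    sub = traj.positions[:, a: a + glen, :].astype(np.int64)
    d = sub[:, 1:, :] - sub[:, :-1, :]
    d = d - np.round(d / dims).astype(np.int64) * dims  # min-image bonds
    unwrapped = np.concatenate(
        [np.zeros((sub.shape[0], 1, 3)), np.cumsum(d, axis=1)], axis=1)
    rm = unwrapped.mean(axis=1, keepdims=True)
    rg_lat = np.sqrt(((unwrapped - rm) ** 2).sum(axis=2).mean(axis=1))
    return rg_lat * traj.params.bond_nm / np.sqrt(2.0)


def msd(trajs: list[PolymerTrajectory] | PolymerTrajectory,
        span: tuple[int, int], n_lags: int = 24,
        interior_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Time- and ensemble-averaged MSD over log-spaced lags.

    Returns ``(lags_mcs, msd)`` with the MSD in squared lattice grid units.
    ``span`` selects the analyzed monomers (absolute indices); with
    ``interior_only`` the outer quarter on each side is dropped to avoid end
    effects of the analyzed subchain.
    """
    if isinstance(trajs, PolymerTrajectory):
        trajs = [trajs]
    t0 = trajs[0]
    g0, glen = span
    a, b = g0 - t0.record_lo, g0 - t0.record_lo + glen
    if interior_only and glen >= 8:
        q = glen // 4
        a, b = a + q, b - q
    n_frames = min(t.positions.shape[0] for t in trajs)
    max_lag = n_frames - 1
    lags = np.unique(np.round(np.logspace(0, np.log10(max_lag),
                                          n_lags)).astype(int))
    out = np.zeros(len(lags))
    for k, lag in enumerate(lags):
        acc, cnt = 0.0, 0
        for t in trajs:
            ps = t.positions[:n_frames, a:b, :].astype(float)
            d = ps[lag:] - ps[:-lag]
            acc += (d ** 2).sum(axis=2).mean() * d.shape[0] * d.shape[1]
            cnt += d.shape[0] * d.shape[1]
        out[k] = acc / cnt
    return lags * t0.snapshot_every, out


@dataclass
class MsdFit:
    """Power-law fit MSD = D * lag^delta (log-log least squares)."""

    D: float
    delta: float
    residual: float
    lag_window: tuple[float, float]


def fit_powerlaw(lags: np.ndarray, values: np.ndarray,
                 lag_window: tuple[float, float] | None = None) -> MsdFit:
    """Linear least squares in log-log space over the given lag window."""
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if lag_window is None:
        lag_window = (lags.min(), lags.max())
    keep = (lags >= lag_window[0]) & (lags <= lag_window[1]) & (values > 0)
    if keep.sum() < 2:
        raise ValueError("need at least two positive MSD points in the window")
    x, y = np.log(lags[keep]), np.log(values[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return MsdFit(D=float(np.exp(intercept)), delta=float(slope),
                  residual=resid, lag_window=lag_window)


def calibrate_time(fit: MsdFit, bond_nm: float = 50.0,
                   target_prefactor: float = 0.01,
                   target_delta: float = 0.5,
                   delta_tol: float = 0.1) -> float:
    """Seconds per MCS matching a reference MSD prefactor (um^2/s^delta).

    The fit must be in lattice grid units per MCS with an exponent close to
    the reference ``target_delta`` (default the Rouse-like 0.5 seen in
    live imaging); otherwise the calibration is refused.  Solves
    ``D_lat * c / tau^delta = target`` for tau, with ``c`` the um^2 per
    squared grid unit.
    """
    if not np.isfinite(fit.delta) or abs(fit.delta - target_delta) > delta_tol:
        raise ValueError(
            f"diffusion exponent {fit.delta:.3f} too far from "
            f"{target_delta}; time calibration against a t^{target_delta} "
            "reference would be ill-defined"
        )
    c = (bond_nm / np.sqrt(2.0) / 1000.0) ** 2  # um^2 per grid unit^2
    return float((fit.D * c / target_prefactor) ** (1.0 / fit.delta))


def burst_conditioned_stats(traj: PolymerTrajectory, span: tuple[int, int],
                            gene_index: int = 0) -> dict:
    """Structure statistics conditioned on the promoter state.

    Returns RG samples split by on/off promoter state, the Spearman rank
    correlation between instantaneous Pol II density on the gene and RG, and
    the histogram of concurrent train counts.
    """
    rg = rg_series(traj, span)
    on = traj.promoter[:, gene_index].astype(bool)
    g0, glen = span
    a = g0 - traj.record_lo
    density = traj.occupancy[:, a: a + glen].mean(axis=1)
    if np.ptp(density) > 0 and np.ptp(rg) > 0:
        rho, p = stats.spearmanr(density, rg)
    else:
        rho, p = float("nan"), float("nan")
    trains = traj.trains[:, gene_index]
    hist = np.bincount(trains, minlength=int(trains.max()) + 1 if trains.size else 1)
    return {
        "rg_on": rg[on], "rg_off": rg[~on],
        "density": density, "rg": rg,
        "density_rg_spearman": float(rho), "p_value": float(p),
        "train_histogram": hist,
    }


def inter_gene_analysis(traj: PolymerTrajectory, span1: tuple[int, int],
                        span2: tuple[int, int],
                        region: tuple[int, int] | None = None) -> dict:
    """Contact enrichment between two gene spans versus matched-distance background.

    Computes the obs/exp map of the recorded region with both gene spans and
    their cross pairs excluded from the expected estimate, then summarizes
    the cross-gene block: overall mean enrichment, body-body core (central
    halves), TSS-TTS corner pixels, and a flank-flank reference at matching
    separation.
    """
    lo, hi = region if region is not None else (traj.record_lo, traj.record_hi)
    cmap = sim_contact_map(traj, lo, hi)
    a1, b1 = span1[0] - lo, span1[0] - lo + span1[1]
    a2, b2 = span2[0] - lo, span2[0] - lo + span2[1]
    oe = sim_obs_exp(cmap, exclude_spans=[(a1, b1), (a2, b2)])
    cross = oe.values[a1:b1, a2:b2]
    l1, l2 = span1[1], span2[1]
    core = cross[l1 // 4: l1 - l1 // 4, l2 // 4: l2 - l2 // 4]
    # flank-flank reference: upstream flank of gene 1 vs downstream of gene 2,
    # same separation as the gene pair
    f1_lo, f1_hi = max(a1 - l1, 0), a1
    f2_lo, f2_hi = b2, min(b2 + l2, oe.n_bins)
    flank = oe.values[f1_lo:f1_hi, f2_lo:f2_hi]
    out = {
        "cross_block": cross,
        "mean_enrichment": float(np.nanmean(cross)),
        "body_body_mean": float(np.nanmean(core)),
        "flank_flank_mean": float(np.nanmean(flank)) if flank.size else float("nan"),
        "tss1_tss2": float(cross[0, 0]),
        "tss1_tts2": float(cross[0, -1]),
        "tts1_tss2": float(cross[-1, 0]),
        "tts1_tts2": float(cross[-1, -1]),
    }
    return out


def unwrap_chain(positions: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Remove periodic jumps by following bond vectors from monomer 1.

    ``positions`` is (M, 3) wrapped coordinates of a connected subchain.
    """
    pos = np.asarray(positions, dtype=np.int64)
    dims = np.asarray(dims, dtype=np.int64)
    out = pos.copy()
    for i in range(1, pos.shape[0]):
        d = pos[i] - pos[i - 1]
        d = d - np.round(d / dims).astype(np.int64) * dims
        out[i] = out[i - 1] + d
    return out
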
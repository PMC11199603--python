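"""Binned contact matrices and distance normalization.

A :class:`ContactMatrix` holds a symmetric, non-negative matrix of contact
counts binned at a fixed genomic resolution, together with a per-bin validity
mask (bins removed from all averages, e.g. unmappable regions).  Its
distance-normalized form, the :class:`ObsExpMatrix`, divides each pixel by the
mean contact frequency at the same genomic separation, so that enrichment is
measured against the sequence-averaged null decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ContactMatrix",
    "ObsExpMatrix",
    "compute_expected",
    "compute_obs_exp",
    "read_dense",
    "write_dense",
    "read_triplet",
    "write_triplet",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix for one chromosome/region.

    Parameters
    ----------
    values
        ``(n, n)`` symmetric, non-negative array of (balanced) contact counts.
    resolution
        Bin size in bp.
    chrom
        Chromosome/region identifier.
    mask
        Boolean ``(n,)`` array, ``True`` marks invalid bins whose rows and
        columns are excluded from every average.
    """

    values: np.ndarray
    resolution: int
    chrom: str = "chrS"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ValueError("mask must be one flag per bin")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        valid = self.values[~np.isnan(self.values)]
        if (valid < 0).any():
            raise ValueError("contact matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos_bp: int) -> int:
        return int(pos_bp) // int(self.resolution)


@dataclass
class ObsExpMatrix:
    """Distance-normalized (observed/expected) contact matrix.

    Entries ``c_ij = obs_ij / expected(|i-j|)``; invalid pixels are NaN.  The
    mean over every diagonal with at least one valid pixel is 1 by
    construction.
    """

    values: np.ndarray
    resolution: int
    chrom: str = "chrS"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos_bp: int) -> int:
        return int(pos_bp) // int(self.resolution)


def compute_expected(m: ContactMatrix) -> np.ndarray:
    """Per-diagonal mean of unmasked entries: the distance-decay vector.

    Returns an array ``expected`` of length ``n_bins`` where ``expected[d]``
    is the mean of valid entries at separation ``d``.  A diagonal with no
    valid entry yields NaN (propagated as masked downstream).
    """
    n = m.n_bins
    valid_bin = ~m.mask
    expected = np.full(n, np.nan)
    vals = m.values
    for d in range(n):
        diag = np.diagonal(vals, offset=d)
        ok = valid_bin[: n - d] & valid_bin[d:] & ~np.isnan(diag)
        if ok.any():
            expected[d] = diag[ok].mean()
    return expected


def compute_obs_exp(m: ContactMatrix) -> ObsExpMatrix:
    """Divide each pixel by the mean contact frequency at its separation.

    Pixels in masked rows/columns, or on diagonals whose expected value is
    undefined or zero, become NaN.
    """
    n = m.n_bins
    expected = compute_expected(m)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp_mat = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = m.values / exp_mat
    oe[~np.isfinite(oe)] = np.nan
    oe[m.mask, :] = np.nan
    oe[:, m.mask] = np.nan
    return ObsExpMatrix(values=oe, resolution=m.resolution, chrom=m.chrom,
                        mask=m.mask.copy())


# -- plain-text I/O ----------------------------------------------------------
#
# Two interchangeable text layouts: a dense whitespace matrix and a sparse
# i/j/value triplet list.  Header comment lines carry chrom, resolution and
# masked bins so a round trip is lossless.

def _header_lines(m: ContactMatrix) -> list[str]:
    masked = ",".join(str(i) for i in np.flatnonzero(m.mask))
    return [
        f"# chrom={m.chrom}",
        f"# resolution={m.resolution}",
        f"# n_bins={m.n_bins}",
        f"# masked_bins={masked}",
    ]


def _parse_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    out = {
        "chrom": meta.get("chrom", "chrS"),
        "resolution": int(meta.get("resolution", 1)),
        "n_bins": int(meta["n_bins"]) if "n_bins" in meta else None,
    }
    masked = meta.get("masked_bins", "")
    out["masked"] = [int(x) for x in masked.split(",") if x != ""]
    return out


def write_dense(m: ContactMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(m)) + "\n")
        np.savetxt(fh, m.values, fmt="%.17g")


def read_dense(path: str | Path) -> ContactMatrix:
    meta = _parse_header(Path(path))
    values = np.loadtxt(path, comments="#")
    mask = np.zeros(values.shape[0], dtype=bool)
    mask[meta["masked"]] = True
    return ContactMatrix(values=values, resolution=meta["resolution"],
                         chrom=meta["chrom"], mask=mask)


def write_triplet(m: ContactMatrix, path: str | Path) -> None:
    path = Path(path)
    i, j = np.nonzero(np.triu(np.nan_to_num(m.values)))
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(m)) + "\n")
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{m.values[a, b]:.17g}\n")


def read_triplet(path: str | Path) -> ContactMatrix:
    meta = _parse_header(Path(path))
    data = np.loadtxt(path, comments="#", ndmin=2)
    if meta["n_bins"] is None:
        raise ValueError("triplet file must declare n_bins in its header")
    n = meta["n_bins"]
    values = np.zeros((n, n))
    if data.size:
        i = data[:, 0].astype(int)
        j = data[:, 1].astype(int)
        values[i, j] = data[:, 2]
        values[j, i] = data[:, 2]
    mask = np.zeros(n, dtype=bool)
    mask[meta["masked"]] = True
    return ContactMatrix(values=values, resolution=meta["resolution"],
                         chrom=meta["chrom"], mask=mask)
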
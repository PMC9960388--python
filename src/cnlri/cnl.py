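"""Cumulative-neutral-loss (CNL) featurization.

A spectrum's cumulative neutral losses are all precursor-minus-fragment
mass differences. They are encoded on a fixed mass grid from 0 to
1000 Da with 0.01 Da spacing (100,000 bins, i.e. a +/- 5 mDa tolerance
around each bin center) as a ternary vector:

* ``1``  — at least one loss falls in the bin,
* ``0``  — no loss observed, but a loss of that mass would be possible,
* ``-1`` — the bin's center mass exceeds the precursor ion mass, so a
  loss there is physically impossible.

The -1 band lets a model distinguish "absent" from "impossible". The
precursor ion m/z is appended as one continuous feature, so a full
feature row has 100,001 columns.

Storage is sparse: only the +1 bins are materialized and the -1 band is
kept as a single per-row breakpoint (the first impossible bin index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "CNLGrid",
    "CNLSet",
    "CNLFeatureRow",
    "CNLFeatureMatrix",
    "compute_cnls",
    "encode_row",
    "build_feature_matrix",
    "PRECURSOR_FEATURE",
]

#: Name of the continuous precursor-mass column appended to the bin columns.
PRECURSOR_FEATURE = "precursor_mz"


@dataclass(frozen=True)
class CNLGrid:
    """Fixed loss-mass grid: bin centers at k*step, half-open coverage.

    Defaults give 100,000 bins over [0, 1000) Da with centers at
    k*0.01 Da; assignment is round-half-to-even on ``mass/step``, so any
    loss within 5 mDa of a center maps to that center's bin. Ties at
    exact half-boundaries (e.g. 18.005 Da) follow the rounding rule.
    """

    min_mass: float = 0.0
    max_mass: float = 1000.0
    step: float = 0.01

    def __post_init__(self) -> None:
        n = (self.max_mass - self.min_mass) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid span must be an exact multiple of step")

    @property
    def n_bins(self) -> int:
        return int(round((self.max_mass - self.min_mass) / self.step))

    def bin_index(self, mass: float | np.ndarray) -> np.ndarray:
        """Bin index for a loss mass; valid iff ``0 <= index < n_bins``."""
        return np.rint((np.asarray(mass, dtype=float) - self.min_mass) / self.step).astype(
            np.int64
        )

    def bin_center(self, index: int | np.ndarray) -> np.ndarray:
        return self.min_mass + np.asarray(index, dtype=float) * self.step

    def column_names(self) -> list[str]:
        width = len(str(self.n_bins - 1))
        return [f"cnl_{i:0{width}d}" for i in range(self.n_bins)]


@dataclass(frozen=True)
class CNLSet:
    """The cumulative neutral losses of one spectrum.

    ``losses`` are ``precursor_mz - fragment_mz`` for every fragment at
    or below the precursor; fragments above the precursor are physically
    impossible losses, excluded at construction and counted in
    ``n_excluded``.
    """

    spectrum_id: str
    precursor_mz: float
    losses: tuple[float, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if any(loss < 0 for loss in self.losses):
            raise ValueError("neutral losses must be >= 0")


@dataclass(frozen=True)
class CNLFeatureRow:
    """Ternary encoding of one spectrum on a :class:`CNLGrid`.

    Sparse representation: ``one_bins`` are the indices set to 1;
    ``neg_start`` is the first index of the -1 band (every bin at or
    beyond it has a center strictly above the precursor mass); all other
    entries are 0. ``n_offgrid`` counts losses >= the grid maximum,
    dropped with a warning.
    """

    spectrum_id: str
    one_bins: tuple[int, ...]
    neg_start: int
    precursor_mass_feature: float
    n_bins: int
    n_offgrid: int = 0

    @property
    def vector(self) -> np.ndarray:
        """Materialize the full ternary vector (length ``n_bins``, int8)."""
        v = np.zeros(self.n_bins, dtype=np.int8)
        v[self.neg_start :] = -1
        v[list(self.one_bins)] = 1
        return v


def compute_cnls(s: Spectrum) -> CNLSet:
    """Cumulative neutral losses: subtract fragment masses from the precursor.

    Raises ``ValueError`` for a spectrum without fragments (a usable
    spectrum has at least one).
    """
    if s.n_fragments == 0:
        raise ValueError(f"spectrum {s.spectrum_id!r} has no fragments")
    frag = s.fragment_mz
    possible = frag <= s.precursor_mz
    losses = s.precursor_mz - frag[possible]
    n_excluded = int((~possible).sum())
    if n_excluded:
        logger.debug(
            "spectrum %s: excluded %d fragment(s) above the precursor",
            s.spectrum_id,
            n_excluded,
        )
    return CNLSet(
        spectrum_id=s.spectrum_id,
        precursor_mz=s.precursor_mz,
        losses=tuple(float(x) for x in losses),
        n_excluded=n_excluded,
    )


def _neg_start(precursor_mz: float, grid: CNLGrid) -> int:
    """First bin index whose center mass strictly exceeds the precursor.

    Defined as one past the precursor's own bin, so a loss (always <=
    precursor, hence binned at or below the precursor's bin) can never
    land in the -1 band, even at the rounding boundary.
    """
    return int(min(grid.bin_index(precursor_mz) + 1, grid.n_bins))


def encode_row(c: CNLSet, grid: CNLGrid | None = None) -> CNLFeatureRow:
    """Encode a loss set as the ternary bit vector plus precursor feature."""
    grid = grid or CNLGrid()
    losses = np.asarray(c.losses, dtype=float)
    if losses.size:
        idx = grid.bin_index(losses)
        on_grid = idx < grid.n_bins
        n_offgrid = int((~on_grid).sum())
        if n_offgrid:
            logger.warning(
                "spectrum %s: %d loss(es) at or above %g Da fall off-grid and are dropped",
                c.spectrum_id,
                n_offgrid,
                grid.max_mass,
            )
        one_bins = tuple(int(i) for i in np.unique(idx[on_grid]))
    else:
        one_bins, n_offgrid = (), 0
    return CNLFeatureRow(
        spectrum_id=c.spectrum_id,
        one_bins=one_bins,
        neg_start=_neg_start(c.precursor_mz, grid),
        precursor_mass_feature=c.precursor_mz,
        n_bins=grid.n_bins,
        n_offgrid=n_offgrid,
    )


class CNLFeatureMatrix:
    """Sparse stack of :class:`CNLFeatureRow`, one row per spectrum.

    Column order is bin 0 ... n_bins-1 followed by the precursor-mass
    feature; rows keep the input spectrum order and duplicates are
    preserved. Only +1 entries are stored; the -1 band is reconstructed
    from each row's breakpoint when a dense model matrix is built.
    """

    def __init__(
        self,
        ones: sparse.csr_matrix,
        neg_start: np.ndarray,
        precursor_mz: np.ndarray,
        spectrum_ids: list[str],
        grid: CNLGrid,
    ):
        self.ones = ones.tocsr()
        self.neg_start = np.asarray(neg_start, dtype=np.int64)
        self.precursor_mz = np.asarray(precursor_mz, dtype=float)
        self.spectrum_ids = list(spectrum_ids)
        self.grid = grid

    @property
    def n_rows(self) -> int:
        return self.ones.shape[0]

    @property
    def n_columns(self) -> int:
        """Total feature count: loss bins plus the precursor-mass column."""
        return self.grid.n_bins + 1

    def row(self, i: int) -> CNLFeatureRow:
        return CNLFeatureRow(
            spectrum_id=self.spectrum_ids[i],
            one_bins=tuple(int(j) for j in self.ones[i].indices),
            neg_start=int(self.neg_start[i]),
            precursor_mass_feature=float(self.precursor_mz[i]),
            n_bins=self.grid.n_bins,
        )

    def occupied_bins(self) -> np.ndarray:
        """Sorted bin indices holding at least one loss across all rows."""
        return np.unique(self.ones.indices)

    def to_model_frame(self, bins: Sequence[int] | None = None) -> pd.DataFrame:
        """Dense ternary matrix over ``bins`` plus the precursor column.

        ``bins`` defaults to :meth:`occupied_bins`. Entries are +1 where
        a loss was observed, -1 where the bin center exceeds the row's
        precursor mass, else 0. Restricting to a fixed bin list keeps
        train/predict matrices aligned; for new data pass the training
        bins.
        """
        bins = np.asarray(self.occupied_bins() if bins is None else bins, dtype=np.int64)
        dense = np.asarray(self.ones[:, bins].todense(), dtype=np.float32)
        # -1 band: bin index >= row breakpoint
        impossible = bins[None, :] >= self.neg_start[:, None]
        dense[impossible & (dense == 0)] = -1.0
        width = len(str(self.grid.n_bins - 1))
        cols = [f"cnl_{i:0{width}d}" for i in bins]
        frame = pd.DataFrame(dense, columns=cols, index=self.spectrum_ids)
        frame[PRECURSOR_FEATURE] = self.precursor_mz
        return frame

    def export(self, out_dir: str | Path) -> None:
        """Write the matrix as matrix-market (+1 entries) with metadata CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mmwrite(str(out / "cnl_ones.mtx"), self.ones.astype(np.int8))
        pd.DataFrame(
            {
                "spectrum_id": self.spectrum_ids,
                "precursor_mz": self.precursor_mz,
                "neg_start_bin": self.neg_start,
            }
        ).to_csv(out / "rows.csv", index=False)
        occ = self.occupied_bins()
        pd.DataFrame(
            {
                "column": [f"cnl_{i}" for i in occ] + [PRECURSOR_FEATURE],
                "bin_index": list(occ) + [-1],
                "bin_center_da": list(self.grid.bin_center(occ)) + [float("nan")],
                "is_precursor_feature": [False] * len(occ) + [True],
            }
        ).to_csv(out / "columns.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path, grid: CNLGrid | None = None) -> "CNLFeatureMatrix":
        in_dir = Path(in_dir)
        grid = grid or CNLGrid()
        ones = sparse.csr_matrix(mmread(str(in_dir / "cnl_ones.mtx")))
        rows = pd.read_csv(in_dir / "rows.csv")
        return cls(
            ones,
            rows["neg_start_bin"].to_numpy(),
            rows["precursor_mz"].to_numpy(),
            rows["spectrum_id"].astype(str).tolist(),
            grid,
        )


def build_feature_matrix(
    spectra: Iterable[Spectrum],
    grid: CNLGrid | None = None,
    *,
    skip_invalid: bool = False,
) -> CNLFeatureMatrix:
    """Featurize spectra into a sparse CNL matrix, one row per spectrum.

    Duplicate spectra stay duplicate rows. Spectra without fragments are
    rejected: by default the call fails listing them; with
    ``skip_invalid=True`` they are recorded on the returned matrix's
    ``rejected`` attribute instead (never silently dropped).
    """
    grid = grid or CNLGrid()
    indptr = [0]
    indices: list[int] = []
    neg_start: list[int] = []
    precursor: list[float] = []
    ids: list[str] = []
    rejected: list[str] = []
    for s in spectra:
        try:
            row = encode_row(compute_cnls(s), grid)
        except ValueError:
            rejected.append(s.spectrum_id)
            continue
        indices.extend(row.one_bins)
        indptr.append(len(indices))
        neg_start.append(row.neg_start)
        precursor.append(row.precursor_mass_feature)
        ids.append(row.spectrum_id)
    if rejected and not skip_invalid:
        raise ValueError(f"unusable spectra (no fragments): {rejected}")
    ones = sparse.csr_matrix(
        (np.ones(len(indices), dtype=np.int8), indices, indptr),
        shape=(len(ids), grid.n_bins),
    )
    matrix = CNLFeatureMatrix(ones, np.array(neg_start), np.array(precursor), ids, grid)
    matrix.rejected = rejected
    return matrix
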
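"""Molecular-descriptor table curation.

Descriptor tables (compound x descriptor, e.g. PaDEL output consumed as
CSV) are curated before modeling:

1. rows with non-finite values (typically failed 3D-descriptor
   convergence) are dropped and reported;
2. every descriptor is min-max scaled to [0, 1] jointly across the
   replicate tables;
3. descriptors whose value is not reproducible across replicate
   calculations — across-replicate sample variance (on the scaled
   scale) at or above a threshold, default 0.01 — are dropped.

The fitted scaling parameters and the kept-descriptor list form a
:class:`CurationReport` that is re-applied verbatim to new tables, so a
large un-replicated corpus inherits the stability decisions made on the
replicated training set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorTable",
    "CurationReport",
    "read_descriptor_csv",
    "minmax_scale",
    "stability_filter",
    "apply_curation",
]


@dataclass
class DescriptorTable:
    """A compound x descriptor numeric matrix.

    ``frame`` is indexed by compound_id with unique descriptor-name
    columns; ``replicate_id`` tags one of several repeated descriptor
    calculations of the same compounds.
    """

    frame: pd.DataFrame
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if self.frame.index.duplicated().any():
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")

    @property
    def compounds(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def descriptors(self) -> list[str]:
        return self.frame.columns.tolist()

    def nonconverged_compounds(self) -> list[str]:
        """Compounds with any non-finite descriptor value."""
        finite = np.isfinite(self.frame.to_numpy(dtype=float))
        return self.frame.index[~finite.all(axis=1)].tolist()


def read_descriptor_csv(path: str | Path, replicate_id: int | None = None) -> DescriptorTable:
    """Read a descriptor CSV: first column compound_id, the rest numeric."""
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame = frame.apply(pd.to_numeric, errors="coerce")
    return DescriptorTable(frame, replicate_id=replicate_id)


@dataclass
class CurationReport:
    """Outcome of descriptor curation; re-applicable to new tables.

    ``kept``, ``dropped_unstable`` and ``dropped_nonfinite`` partition
    the input descriptors. ``scaling_params`` maps every kept descriptor
    to the (min, max) fitted jointly across replicates.
    """

    kept: list[str]
    dropped_unstable: dict[str, float]
    dropped_nonfinite: list[str]
    scaling_params: dict[str, tuple[float, float]]
    constant: list[str] = field(default_factory=list)
    dropped_compounds: list[str] = field(default_factory=list)
    threshold: float = 0.01
    aggregate: str = "max"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kept": self.kept,
            "dropped_unstable": self.dropped_unstable,
            "dropped_nonfinite": self.dropped_nonfinite,
            "scaling_params": {k: list(v) for k, v in self.scaling_params.items()},
            "constant": self.constant,
            "dropped_compounds": self.dropped_compounds,
            "threshold": self.threshold,
            "aggregate": self.aggregate,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CurationReport":
        payload = json.loads(Path(path).read_text())
        payload["scaling_params"] = {
            k: (float(v[0]), float(v[1])) for k, v in payload["scaling_params"].items()
        }
        return cls(**payload)


def _fit_minmax(frame: pd.DataFrame) -> tuple[dict[str, tuple[float, float]], list[str]]:
    params: dict[str, tuple[float, float]] = {}
    constant: list[str] = []
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        finite = col[np.isfinite(col)]
        if finite.size == 0:
            raise ValueError(f"descriptor {name!r} has no finite values")
        lo, hi = float(finite.min()), float(finite.max())
        params[name] = (lo, hi)
        if lo == hi:
            constant.append(name)
    return params, constant


def _scale_with(frame: pd.DataFrame, params: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = {}
    for name in frame.columns:
        lo, hi = params[name]
        col = frame[name].to_numpy(dtype=float)
        # constant columns carry no information; mapped to 0 by convention
        out[name] = np.zeros_like(col) if hi == lo else (col - lo) / (hi - lo)
    return pd.DataFrame(out, index=frame.index)


def minmax_scale(t: DescriptorTable) -> tuple[DescriptorTable, dict[str, tuple[float, float]]]:
    """Scale each descriptor to [0, 1] by its own min and max.

    Constant columns (max == min) map to 0 and are logged. Returns the
    scaled table and the per-descriptor (min, max) for reuse on new
    data, where values may legitimately fall outside [0, 1].
    """
    params, constant = _fit_minmax(t.frame)
    if constant:
        logger.info("constant descriptor columns mapped to 0: %s", constant)
    return DescriptorTable(_scale_with(t.frame, params), t.replicate_id), params


def stability_filter(
    replicates: Sequence[DescriptorTable],
    threshold: float = 0.01,
    aggregate: Literal["max", "mean", "pooled"] = "max",
) -> CurationReport:
    """Keep descriptors whose replicate variance stays below ``threshold``.

    All replicate tables are min-max scaled jointly per descriptor, then
    for each descriptor the across-replicate sample variance (ddof=1) is
    computed per compound and aggregated over compounds — ``max``
    (strictest, default), ``mean``, or ``pooled`` (one variance over all
    compound-replicate deviations). A descriptor is kept iff its
    aggregated variance is strictly below the threshold.

    Compounds with non-finite values in any replicate are dropped
    row-wise first and listed in the report.
    """
    if len(replicates) < 2:
        raise ValueError("stability filtering needs at least 2 replicate tables")
    ref = replicates[0]
    for rep in replicates[1:]:
        if set(rep.compounds) != set(ref.compounds):
            diff = set(rep.compounds) ^ set(ref.compounds)
            raise ValueError(f"replicates disagree on compound ids: {sorted(diff)}")
        if list(rep.descriptors) != list(ref.descriptors):
            diff = set(rep.descriptors) ^ set(ref.descriptors)
            raise ValueError(f"replicates disagree on descriptors: {sorted(diff)}")

    frames = [r.frame.loc[ref.compounds] for r in replicates]
    dropped_compounds = sorted(
        {c for f in frames for c in DescriptorTable(f).nonconverged_compounds()}
    )
    if dropped_compounds:
        logger.info("dropping %d non-converged compound(s)", len(dropped_compounds))
        keep_rows = [c for c in ref.compounds if c not in set(dropped_compounds)]
        frames = [f.loc[keep_rows] for f in frames]

    dropped_nonfinite = [
        name
        for name in ref.descriptors
        if not all(np.isfinite(f[name].to_numpy(dtype=float)).all() for f in frames)
    ]
    names = [n for n in ref.descriptors if n not in set(dropped_nonfinite)]

    joint = pd.concat([f[names] for f in frames], axis=0)
    params, constant = _fit_minmax(joint)
    scaled = np.stack([_scale_with(f[names], params).to_numpy() for f in frames])  # r x n x p

    per_compound_var = scaled.var(axis=0, ddof=1)  # n x p
    if aggregate == "max":
        agg = per_compound_var.max(axis=0)
    elif aggregate == "mean":
        agg = per_compound_var.mean(axis=0)
    elif aggregate == "pooled":
        dev = scaled - scaled.mean(axis=0, keepdims=True)
        agg = (dev**2).sum(axis=(0, 1)) / (dev.shape[0] * dev.shape[1] - 1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")

    kept, dropped_unstable = [], {}
    for j, name in enumerate(names):
        if agg[j] < threshold:  # strictly below: "variance lower than" the cutoff
            kept.append(name)
        else:
            dropped_unstable[name] = float(agg[j])
    if dropped_unstable:
        logger.info("dropped %d unstable descriptor(s)", len(dropped_unstable))
    return CurationReport(
        kept=kept,
        dropped_unstable=dropped_unstable,
        dropped_nonfinite=dropped_nonfinite,
        scaling_params={k: params[k] for k in kept},
        constant=[c for c in constant if c in set(kept)],
        dropped_compounds=dropped_compounds,
        threshold=threshold,
        aggregate=aggregate,
    )


def apply_curation(t: DescriptorTable, report: CurationReport) -> DescriptorTable:
    """Restrict a table to the kept descriptors, scaled with stored params.

    New data may fall outside the fitted range; values are not clipped.
    """
    missing = [c for c in report.kept if c not in t.frame.columns]
    if missing:
        raise ValueError(f"table is missing kept descriptor column(s): {missing}")
    sub = t.frame[report.kept]
    return DescriptorTable(_scale_with(sub, report.scaling_params), t.replicate_id)
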
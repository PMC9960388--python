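"""Reading and writing tandem-MS spectra (MSP / MGF text formats).

Spectra are thin immutable records around what the downstream
neutral-loss featurization needs: a precursor ion m/z and a fragment
peak list. Parsing of the text dialects is delegated to :mod:`matchms`;
this module adds record-level validation, skip accounting and the
internal :class:`Spectrum` type.

Notes on semantics
------------------
* The precursor ion m/z is used as given; ions are assumed singly
  charged, so neutral-loss masses are computed directly in m/z space and
  no adduct arithmetic is applied.
* Duplicate records — even byte-identical ones — are kept as separate
  :class:`Spectrum` instances; redundant spectra of one compound carry
  real information about fragmentation variability.
* Fragment peaks are stored in ascending m/z order (the canonical order
  used by matchms). Intensities are retained but the featurization is
  presence/absence only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from matchms import Spectrum as _MatchmsSpectrum
from matchms.exporting import save_as_msp as _save_as_msp
from matchms.importing import load_from_mgf as _load_from_mgf
from matchms.importing import load_from_msp as _load_from_msp

logger = logging.getLogger(__name__)

__all__ = ["Spectrum", "SpectrumCollection", "read_msp", "read_mgf", "write_msp"]


@dataclass(frozen=True)
class Spectrum:
    """One measured MS/MS record.

    Parameters
    ----------
    spectrum_id:
        Opaque identifier, unique within a parsed file.
    precursor_mz:
        Precursor ion m/z in Da; must be positive.
    fragments:
        ``(mz, intensity)`` pairs, ascending in m/z. A usable spectrum
        has at least one fragment; readers never emit empty ones.
    compound_id:
        InChIKey (preferred) or SMILES when present in the metadata;
        matched case-sensitively against label tables. ``None`` for
        unidentified spectra (prediction use-case).
    """

    spectrum_id: str
    precursor_mz: float
    fragments: tuple[tuple[float, float], ...]
    compound_id: str | None = None
    adduct: str | None = None
    instrument_meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.precursor_mz > 0):
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        for mz, intensity in self.fragments:
            if not (mz > 0):
                raise ValueError(f"fragment m/z must be positive, got {mz}")
            if intensity < 0:
                raise ValueError(f"fragment intensity must be >= 0, got {intensity}")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def fragment_mz(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.fragments], dtype=float)


class SpectrumCollection(Sequence):
    """Spectra parsed from one file plus the records that were skipped.

    Behaves as a sequence of :class:`Spectrum`. ``skipped`` holds
    ``(record_label, reason)`` pairs; nothing is dropped silently.
    """

    def __init__(self, spectra: list[Spectrum], skipped: list[tuple[str, str]]):
        self._spectra = list(spectra)
        self.skipped = list(skipped)

    def __len__(self) -> int:
        return len(self._spectra)

    def __getitem__(self, i):
        return self._spectra[i]

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self._spectra)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpectrumCollection({len(self)} spectra, {self.n_skipped} skipped)"


def _from_matchms(ms, spectrum_id: str) -> Spectrum:
    meta = dict(ms.metadata)
    compound_id = meta.get("inchikey") or meta.get("smiles") or None
    if compound_id is not None:
        compound_id = str(compound_id).strip() or None
    fragments = tuple(
        (float(mz), float(intensity))
        for mz, intensity in zip(ms.peaks.mz, ms.peaks.intensities)
    )
    reserved = {"precursor_mz", "inchikey", "smiles", "adduct", "spectrum_id"}
    instrument_meta = {k: str(v) for k, v in meta.items() if k not in reserved}
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=float(meta["precursor_mz"]),
        fragments=fragments,
        compound_id=compound_id,
        adduct=meta.get("adduct"),
        instrument_meta=instrument_meta,
    )


def _validate(ms, label: str) -> str | None:
    """Return a skip reason for a parsed matchms spectrum, or None if usable."""
    if ms is None:
        return "unparseable record"
    meta = ms.metadata
    pmz = meta.get("precursor_mz")
    try:
        pmz = float(pmz)
    except (TypeError, ValueError):
        pmz = None
    if pmz is None or not np.isfinite(pmz) or pmz <= 0:
        return "missing or unparseable precursor m/z"
    if ms.peaks is None or len(ms.peaks.mz) == 0:
        return "no fragment peaks"
    if np.any(ms.peaks.mz <= 0):
        return "non-positive fragment m/z"
    return None


def _split_msp_blocks(text: str) -> list[str]:
    """Split MSP text into blank-line-delimited record blocks.

    matchms parses whole files; feeding it one record at a time keeps a
    malformed record (e.g. ``Num Peaks: 0``) from bleeding metadata into
    its neighbour and lets every skip be attributed to its record.
    """
    blocks, current = [], []
    for line in text.splitlines():
        if line.strip():
            current.append(line)
        elif current:
            blocks.append("\n".join(current))
            current = []
    if current:
        blocks.append("\n".join(current))
    return blocks


def read_msp(path: str | Path) -> SpectrumCollection:
    """Read an MSP (NIST text dialect) spectral library.

    One :class:`Spectrum` per well-formed record, in file order.
    Records without a parseable precursor m/z or without peaks are
    skipped, counted and logged — never silently dropped.
    """
    path = Path(path)
    text = path.read_text()  # unreadable file raises OSError
    spectra: list[Spectrum] = []
    skipped: list[tuple[str, str]] = []
    stem = path.stem
    import tempfile

    for i, block in enumerate(_split_msp_blocks(text)):
        label = f"{stem}#{i}"
        with tempfile.NamedTemporaryFile("w", suffix=".msp", delete=False) as tmp:
            tmp.write(block + "\n")
            tmp_path = tmp.name
        try:
            parsed = list(_load_from_msp(tmp_path, metadata_harmonization=True))
        except Exception as exc:  # malformed block: record-level skip
            logger.warning("skipping MSP record %s: %s", label, exc)
            skipped.append((label, f"parse error: {exc}"))
            continue
        finally:
            Path(tmp_path).unlink(missing_ok=True)
        ms = parsed[0] if parsed else None
        reason = _validate(ms, label)
        if reason == "unparseable record" and _declares_zero_peaks(block):
            reason = "no fragment peaks (Num Peaks: 0)"
        if reason is not None:
            logger.warning("skipping MSP record %s: %s", label, reason)
            skipped.append((label, reason))
            continue
        sid = str(ms.metadata.get("spectrum_id") or "").strip() or label
        spectra.append(_from_matchms(ms, sid))
    return SpectrumCollection(spectra, skipped)


def _declares_zero_peaks(block: str) -> bool:
    for line in block.splitlines():
        key, _, value = line.partition(":")
        if key.strip().lower() == "num peaks":
            return value.strip() == "0"
    return False


def read_mgf(path: str | Path) -> SpectrumCollection:
    """Read an MGF file (``BEGIN IONS``/``END IONS`` blocks, PEPMASS precursor).

    Same contract as :func:`read_msp`: blocks without a parseable
    precursor or without peaks are skipped with a logged reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    skipped: list[tuple[str, str]] = []
    stem = path.stem
    for i, ms in enumerate(_load_from_mgf(str(path), metadata_harmonization=True)):
        label = f"{stem}#{i}"
        reason = _validate(ms, label)
        if reason is not None:
            logger.warning("skipping MGF record %s: %s", label, reason)
            skipped.append((label, reason))
            continue
        meta = ms.metadata
        sid = str(meta.get("spectrum_id") or meta.get("title") or "").strip() or label
        spectra.append(_from_matchms(ms, sid))
    return SpectrumCollection(spectra, skipped)


def write_msp(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to MSP. Minimal writer for fixtures and round-trips."""
    path = Path(path)
    converted = []
    for s in spectra:
        meta = {
            "compound_name": s.spectrum_id,
            "spectrum_id": s.spectrum_id,
            "precursor_mz": s.precursor_mz,
        }
        if s.compound_id is not None:
            # InChIKeys are dash-separated blocks; anything else is SMILES
            key = "inchikey" if _looks_like_inchikey(s.compound_id) else "smiles"
            meta[key] = s.compound_id
        if s.adduct is not None:
            meta["adduct"] = s.adduct
        converted.append(
            _MatchmsSpectrum(
                mz=np.array([mz for mz, _ in s.fragments], dtype=float),
                intensities=np.array([it for _, it in s.fragments], dtype=float),
                metadata=meta,
                metadata_harmonization=False,
            )
        )
    path.unlink(missing_ok=True)  # save_as_msp appends to existing files
    _save_as_msp(converted, str(path))


def _looks_like_inchikey(s: str) -> bool:
    parts = s.split("-")
    return len(parts) in (2, 3) and all(p.isalnum() and p.isupper() for p in parts[:2])
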
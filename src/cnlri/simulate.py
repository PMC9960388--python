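"""Self-contained synthetic world for end-to-end testing.

Real inputs to the two-stage workflow are (a) replicated molecular-
descriptor tables, (b) an MS/MS spectral corpus and (c) experimental
retention-index labels for a subset of compounds. This module generates
all three from a single latent "retention-driving" variable per
compound — a hydrophobicity surrogate — with known ground truth, so
every stage (curation, the descriptor model, the applicability domain,
CNL featurization, pseudo-labeling, the CNL model) can be exercised and
checked against the generating process without any external data.

The generating rules:

* descriptors are affine functions of the latent plus i.i.d. noise,
  with pure-noise decoy columns and a designed set of replicate-
  unstable columns the curation step must remove;
* each compound's precursor mass increases with the latent, and its
  spectra contain characteristic neutral losses from a fixed vocabulary
  whose inclusion probabilities are monotone in the latent, plus
  uniform decoy losses;
* r_i = a + b * sigmoid(latent) + Gaussian noise, spanning roughly the
  200-1041 unit range of an alkylamide retention-index scale.

A designated group of compounds is generated outside the descriptor
distribution to exercise applicability-domain rejection. The world is
fully reproducible from its seed, in memory and on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .spectra import Spectrum, write_msp

__all__ = ["WorldParams", "SyntheticWorld", "generate_world", "oracle_ri", "write_world"]

#: Neutral-loss vocabulary (Da). Includes losses typical of small-molecule
#: fragmentation: water (18.011), CO (27.995), HCl (35.977), CO2 (43.990),
#: formic acid / NO2 (46.005), C4H8 (56.063), SO2 (65.97), SO3 (79.957),
#: and a sulfanilyl-like 155.00 Da moiety, among others.
DEFAULT_LOSS_VOCABULARY = (
    18.011, 27.995, 35.977, 43.990, 46.005, 56.063,
    59.037, 65.97, 72.058, 79.957, 98.984, 155.00,
)


@dataclass(frozen=True)
class WorldParams:
    """Generating parameters of the synthetic world.

    The retention-index rule is ``r_i = ri_a + ri_b * sigmoid(latent) +
    N(0, ri_noise_sd)`` with the latent standard normal. With the
    defaults the signal spans ~200-1041 r_i units with noise on the
    scale of the residual errors typical of descriptor-based retention
    models (tens of r_i units), leaving a noise-ceiling R^2 around 0.9.
    """

    n_compounds: int = 300
    n_experimental: int = 120
    n_ood: int = 15
    n_informative: int = 25
    n_decoy: int = 25
    n_unstable: int = 10
    n_replicates: int = 3
    descriptor_noise_sd: float = 0.15
    replicate_noise_sd: float = 0.03
    unstable_replicate_noise_sd: float = 3.0
    ood_offset: float = 8.0
    ri_a: float = 200.0
    ri_b: float = 841.0
    ri_noise_sd: float = 45.0
    precursor_center: float = 300.0
    precursor_slope: float = 80.0
    precursor_noise_sd: float = 15.0
    fragment_mass_error_sd: float = 0.002
    max_spectra_per_compound: int = 3
    loss_vocabulary: tuple[float, ...] = DEFAULT_LOSS_VOCABULARY
    vocab_slope: float = 2.0
    min_decoy_losses: int = 2
    max_decoy_losses: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 20:
            raise ValueError("n_compounds must be >= 20")
        if not (0 < self.n_experimental < self.n_compounds):
            raise ValueError("n_experimental must lie strictly inside n_compounds")
        if self.n_ood > self.n_compounds - self.n_experimental:
            raise ValueError("n_ood cannot exceed the corpus size")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticWorld:
    params: WorldParams
    compound_ids: list[str]
    latent: dict[str, float]
    ri_true: dict[str, float]
    ri_observed: dict[str, float]
    experimental_ids: list[str]
    corpus_ids: list[str]
    ood_ids: list[str]
    replicate_tables: list[DescriptorTable]
    corpus_table: DescriptorTable
    spectra: list[Spectrum]
    informative_descriptors: list[str]
    decoy_descriptors: list[str]
    unstable_descriptors: list[str]
    vocab_effects: dict[float, tuple[float, float]]

    @property
    def labels(self) -> pd.DataFrame:
        """Experimental r_i labels (compound_id, r_i) — the measured subset."""
        return pd.DataFrame(
            {
                "compound_id": self.experimental_ids,
                "r_i": [self.ri_observed[c] for c in self.experimental_ids],
            }
        )


def oracle_ri(world: SyntheticWorld, compound_id: str) -> float:
    """Noise-free expected r_i of a compound: a + b * sigmoid(latent)."""
    if compound_id not in world.latent:
        raise KeyError(f"unknown compound {compound_id!r}")
    p = world.params
    return float(p.ri_a + p.ri_b * _sigmoid(np.array(world.latent[compound_id])))


def _descriptor_base(
    latent: np.ndarray, params: WorldParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """Compound-level descriptor values (before replicate noise)."""
    n = latent.size
    cols: dict[str, np.ndarray] = {}
    informative, decoys, unstable = [], [], []
    for j in range(params.n_informative):
        name = f"phys_{j:02d}"
        slope = rng.uniform(0.5, 1.5) * (1 if j % 2 == 0 else -1)
        cols[name] = slope * latent + rng.uniform(-1, 1) + rng.normal(
            0, params.descriptor_noise_sd, n
        )
        informative.append(name)
    for j in range(params.n_decoy):
        name = f"noise_{j:02d}"
        cols[name] = rng.normal(0, 1, n)
        decoys.append(name)
    for j in range(params.n_unstable):
        name = f"unstable_{j:02d}"
        cols[name] = rng.normal(0, 1, n)
        unstable.append(name)
    return pd.DataFrame(cols), informative, decoys, unstable


def generate_world(params: WorldParams | None = None, seed: int | None = None) -> SyntheticWorld:
    """Generate the full synthetic world (descriptors, spectra, labels).

    ``seed`` overrides ``params.seed``. Same seed, same world —
    bit-identical arrays and files.
    """
    params = params or WorldParams()
    if seed is not None:
        params = WorldParams(**{**params.__dict__, "seed": int(seed)})
    rng = np.random.default_rng(params.seed)
    n = params.n_compounds
    ids = [f"CMP{i:04d}-SYN" for i in range(n)]
    latent = rng.normal(0, 1, n)
    ri_true = params.ri_a + params.ri_b * _sigmoid(latent)
    ri_obs = ri_true + rng.normal(0, params.ri_noise_sd, n)

    experimental_ids = ids[: params.n_experimental]
    corpus_ids = ids[params.n_experimental :]
    ood_ids = corpus_ids[len(corpus_ids) - params.n_ood :] if params.n_ood else []
    ood_set = set(ood_ids)

    base, informative, decoys, unstable = _descriptor_base(latent, params, rng)
    base.index = pd.Index(ids)
    # out-of-distribution compounds sit far outside the descriptor cloud
    base.loc[list(ood_ids), informative] += params.ood_offset

    exp_base = base.loc[experimental_ids]
    replicate_tables = []
    for r in range(params.n_replicates):
        noise = rng.normal(0, params.replicate_noise_sd, exp_base.shape)
        rep = exp_base + noise
        uns_noise = rng.normal(
            0, params.unstable_replicate_noise_sd, (len(experimental_ids), len(unstable))
        )
        rep.loc[:, unstable] = exp_base[unstable] + uns_noise
        replicate_tables.append(DescriptorTable(rep, replicate_id=r + 1))
    corpus_frame = base.loc[corpus_ids] + rng.normal(
        0, params.replicate_noise_sd, (len(corpus_ids), base.shape[1])
    )
    corpus_table = DescriptorTable(corpus_frame)

    # loss-vocabulary effects: inclusion log-odds are monotone in the latent,
    # alternating direction so high and low r_i both carry characteristic losses
    vocab_effects = {}
    for k, mass in enumerate(params.loss_vocabulary):
        slope = params.vocab_slope * (1 if k % 2 == 0 else -1)
        intercept = rng.uniform(-0.8, 0.8)
        vocab_effects[float(mass)] = (float(intercept), float(slope))

    precursor = params.precursor_center + params.precursor_slope * latent
    precursor = precursor + rng.normal(0, params.precursor_noise_sd, n)
    precursor = np.clip(precursor, 170.0, 950.0)

    spectra: list[Spectrum] = []
    for i, cid in enumerate(ids):
        n_spec = int(rng.integers(1, params.max_spectra_per_compound + 1))
        for s in range(n_spec):
            pmz = float(precursor[i])
            losses = []
            for mass, (a_k, b_k) in vocab_effects.items():
                p_incl = _sigmoid(np.array(a_k + b_k * latent[i]))
                if rng.random() < p_incl and mass < pmz - 1.0:
                    losses.append(mass)
            n_decoy = int(rng.integers(params.min_decoy_losses, params.max_decoy_losses + 1))
            hi = min(pmz - 5.0, 400.0)
            losses.extend(rng.uniform(10.0, hi, n_decoy).tolist())
            frag_mz = pmz - np.asarray(losses) + rng.normal(
                0, params.fragment_mass_error_sd, len(losses)
            )
            if rng.random() < 0.7:  # surviving precursor ion
                frag_mz = np.append(frag_mz, pmz)
            intensities = rng.uniform(1.0, 100.0, frag_mz.size)
            order = np.argsort(frag_mz)
            spectra.append(
                Spectrum(
                    spectrum_id=f"{cid}_s{s}",
                    precursor_mz=round(pmz, 4),
                    fragments=tuple(
                        (round(float(mz), 4), round(float(it), 1))
                        for mz, it in zip(frag_mz[order], intensities[order])
                    ),
                    compound_id=cid,
                )
            )

    return SyntheticWorld(
        params=params,
        compound_ids=ids,
        latent=dict(zip(ids, latent.astype(float))),
        ri_true=dict(zip(ids, ri_true.astype(float))),
        ri_observed=dict(zip(ids, ri_obs.astype(float))),
        experimental_ids=experimental_ids,
        corpus_ids=corpus_ids,
        ood_ids=list(ood_ids),
        replicate_tables=replicate_tables,
        corpus_table=corpus_table,
        spectra=spectra,
        informative_descriptors=informative,
        decoy_descriptors=decoys,
        unstable_descriptors=unstable,
        vocab_effects=vocab_effects,
    )


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write the world as files readable by every upstream module.

    Emits one descriptor CSV per replicate, a corpus descriptor CSV, an
    r_i label CSV (experimental compounds only) and one MSP spectral
    library. Reproducible: same world, byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for rep in world.replicate_tables:
        p = out / f"descriptors_rep{rep.replicate_id}.csv"
        rep.frame.rename_axis("compound_id").to_csv(p, float_format="%.6f")
        paths[f"descriptors_rep{rep.replicate_id}"] = p
    p = out / "corpus_descriptors.csv"
    world.corpus_table.frame.rename_axis("compound_id").to_csv(p, float_format="%.6f")
    paths["corpus_descriptors"] = p
    p = out / "labels.csv"
    world.labels.round({"r_i": 3}).to_csv(p, index=False)
    paths["labels"] = p
    p = out / "spectra.msp"
    write_msp(world.spectra, p)
    paths["spectra"] = p
    return paths
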
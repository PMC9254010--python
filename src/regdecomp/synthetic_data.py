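"""Synthetic five-genotype count data with known ground truth.

The generator emulates the knockout/replacement design: negative-binomial
counts for mel WT, mel KO, replacement, sim WT and sim KO, with a per-gene
baseline, a genomic-context shift between species backgrounds, and
genotype-specific regulator effects.  KO genotypes are effect-free
baselines; the replacement genotype is the mel background plus the foreign
regulator's effect.  Expected log2 normalized means:

========================  =================================
genotype                  log2 mean
========================  =================================
mel KO                    baseline
mel WT                    baseline + c_g   (native regulator)
replacement               baseline + b_g   (foreign regulator, mel context)
sim KO                    baseline + k_g   (context shift)
sim WT                    baseline + k_g + a_g
========================  =================================

so the generative triple (a_g, b_g, c_g) is exactly what contrasts A, B, C
estimate, the true context effect is b_g - a_g and the true regulator
effect is c_g - b_g.  Counts are NB with variance mu + phi * mu^2; fixed
seeds give bit-reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .counts_io import (
    DESIGN_CELLS,
    STAGES,
    TISSUE,
    CountMatrix,
    OrthologMap,
    SampleSheet,
)

#: Per-genotype-cell mix of the generative effects into the log2 mean:
#: (carries context shift, effect index into (a, b, c) or None for KO).
_CELL_EFFECTS = {
    ("mel", "WT"): (False, 2),
    ("mel", "KO"): (False, None),
    ("mel", "replacement"): (False, 1),
    ("sim", "WT"): (True, 0),
    ("sim", "KO"): (True, None),
}

POISSON_EPS = 1e-12


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated five-genotype experiment.

    ``effect_arch`` is an (n_genes, 3) array of log2 shifts (a_g, b_g, c_g)
    for the sim-background, replacement and mel-background regulator
    variants; ``context_shift`` holds the per-gene log2 shift k_g between
    species backgrounds.  ``dispersion`` may be a scalar or per-gene array.
    ``extra_log2_noise_sd`` adds per-replicate, per-gene normal noise (log2
    scale) to selected (species, genotype) cells, emulating a noisier
    genotype (e.g. extra technical variance in the replacement line).
    """

    n_genes: int
    n_replicates: int = 3
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    dispersion: float | np.ndarray = 0.05
    effect_arch: np.ndarray | None = None
    context_shift: np.ndarray | None = None
    library_size_factors: np.ndarray | None = None
    extra_log2_noise_sd: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError(
                "n_replicates must be >=2: downstream variance estimation "
                "needs replication"
            )
        arch = (
            np.zeros((self.n_genes, 3))
            if self.effect_arch is None
            else np.asarray(self.effect_arch, dtype=float)
        )
        if arch.shape != (self.n_genes, 3):
            raise ValueError("effect_arch must have shape (n_genes, 3)")
        if not np.isfinite(arch).all():
            raise ValueError("effect_arch contains non-finite values")
        shift = (
            np.zeros(self.n_genes)
            if self.context_shift is None
            else np.asarray(self.context_shift, dtype=float)
        )
        if shift.shape != (self.n_genes,):
            raise ValueError("context_shift must have length n_genes")
        if not np.isfinite(shift).all():
            raise ValueError("context_shift contains non-finite values")
        phi = np.broadcast_to(
            np.asarray(self.dispersion, dtype=float), (self.n_genes,)
        ).copy()
        if (phi < 0).any():
            raise ValueError("dispersions must be >= 0")
        n_samples = 5 * self.n_replicates
        sf = (
            np.ones(n_samples)
            if self.library_size_factors is None
            else np.asarray(self.library_size_factors, dtype=float)
        )
        if sf.shape != (n_samples,):
            raise ValueError(
                f"library_size_factors must have length {n_samples}"
            )
        if (sf <= 0).any():
            raise ValueError("library size factors must be positive")
        lo, hi = self.baseline_log2_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("invalid baseline_log2_mean_range")
        object.__setattr__(self, "effect_arch", arch)
        object.__setattr__(self, "context_shift", shift)
        object.__setattr__(self, "dispersion", phi)
        object.__setattr__(self, "library_size_factors", sf)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_genes": int(self.n_genes),
            "n_replicates": int(self.n_replicates),
            "baseline_log2_mean_range": [
                float(v) for v in self.baseline_log2_mean_range
            ],
            "dispersion": np.asarray(self.dispersion).tolist(),
            "effect_arch": np.asarray(self.effect_arch).tolist(),
            "context_shift": np.asarray(self.context_shift).tolist(),
            "library_size_factors": np.asarray(
                self.library_size_factors
            ).tolist(),
            "extra_log2_noise_sd": {
                f"{sp}:{gt}": float(sd)
                for (sp, gt), sd in self.extra_log2_noise_sd.items()
            },
            "seed": int(self.seed),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        noise = {
            tuple(k.split(":")): float(v)
            for k, v in (doc.pop("extra_log2_noise_sd", {}) or {}).items()
        }
        arrays = {
            k: np.asarray(doc.pop(k))
            for k in (
                "effect_arch",
                "context_shift",
                "library_size_factors",
                "dispersion",
            )
            if doc.get(k) is not None
        }
        rng = doc.pop("baseline_log2_mean_range")
        return cls(
            baseline_log2_mean_range=(float(rng[0]), float(rng[1])),
            extra_log2_noise_sd=noise,
            **arrays,
            **doc,
        )


def implied_categories(
    effect_arch: np.ndarray, tol: float = 0.0
) -> np.ndarray:
    """Category I-V implied by a generative effect triple (a, b, c).

    Context effect b - a and regulator effect c - b; zero effects give V,
    a single nonzero effect gives I (regulator) or II (context), and when
    both are nonzero the sign of (a - b) * (b - c) separates enhancing
    (III, > 0) from compensating (IV, < 0).
    """
    a, b, c = (effect_arch[:, i] for i in range(3))
    ctx = np.abs(b - a) > tol
    mir = np.abs(c - b) > tol
    prod = (a - b) * (b - c)
    return np.select(
        [~ctx & ~mir, ~ctx & mir, ctx & ~mir, prod > 0],
        ["V", "I", "II", "III"],
        default="IV",
    )


def architecture_from_counts(
    category_counts: Mapping[str, int],
    effect: float = 2.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Effect triples realizing given numbers of genes per category I-V.

    Each gene gets the canonical architecture of its category with log2
    magnitude ``effect``: I (0, 0, e), II (-e, 0, 0), III (-e, 0, e)
    (context and regulator effects in the same direction), IV (e, 0, e)
    (opposite directions), V (0, 0, 0).  When ``rng`` is given, each
    gene's overall sign is flipped with probability 1/2 so effects point
    both ways.
    """
    templates = {
        "I": (0.0, 0.0, 1.0),
        "II": (-1.0, 0.0, 0.0),
        "III": (-1.0, 0.0, 1.0),
        "IV": (1.0, 0.0, 1.0),
        "V": (0.0, 0.0, 0.0),
    }
    unknown = set(category_counts) - set(templates)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    blocks = []
    for cat in ("I", "II", "III", "IV", "V"):
        n = int(category_counts.get(cat, 0))
        if n:
            blocks.append(np.tile(np.asarray(templates[cat]) * effect, (n, 1)))
    arch = np.vstack(blocks) if blocks else np.empty((0, 3))
    if rng is not None and len(arch):
        signs = rng.choice([-1.0, 1.0], size=len(arch))
        arch = arch * signs[:, None]
    return arch


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene generative effects and the category they imply."""

    table: pd.DataFrame

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class SimulatedExperiment:
    """Counts, design sheet and ground truth of one simulated unit."""

    counts: CountMatrix
    sheet: SampleSheet
    truth: SyntheticTruth
    config: SimConfig


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _sample_layout(n_replicates: int, stage: str) -> pd.DataFrame:
    rows = []
    for species, genotype in DESIGN_CELLS:
        for r in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{species}_{genotype}_{stage}_{r}",
                    "species": species,
                    "genotype": genotype,
                    "stage": stage,
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_experiment(
    config: SimConfig, stage: str = TISSUE
) -> SimulatedExperiment:
    """Simulate NB counts for the five genotypes of one analysis unit."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    lo, hi = config.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=n)
    layout = _sample_layout(config.n_replicates, stage)
    phi = np.asarray(config.dispersion)
    arch = np.asarray(config.effect_arch)
    shift = np.asarray(config.context_shift)

    cols = {}
    for j, (sample_id, row) in enumerate(layout.iterrows()):
        cell = (row["species"], row["genotype"])
        in_sim, eff_idx = _CELL_EFFECTS[cell]
        log2_mean = baseline.copy()
        if in_sim:
            log2_mean += shift
        if eff_idx is not None:
            log2_mean += arch[:, eff_idx]
        noise_sd = config.extra_log2_noise_sd.get(cell, 0.0)
        if noise_sd > 0:
            log2_mean = log2_mean + rng.normal(0.0, noise_sd, size=n)
        mean = np.exp2(log2_mean) * config.library_size_factors[j]
        counts = np.empty(n, dtype=np.int64)
        pois = phi <= POISSON_EPS
        if pois.any():
            counts[pois] = rng.poisson(mean[pois])
        if (~pois).any():
            r = 1.0 / phi[~pois]
            p = r / (r + mean[~pois])
            counts[~pois] = rng.negative_binomial(r, p)
        cols[sample_id] = counts

    counts_df = pd.DataFrame(cols, index=_gene_ids(n))
    counts_df.index.name = "gene_id"
    truth_df = pd.DataFrame(
        {
            "A_true": arch[:, 0],
            "B_true": arch[:, 1],
            "C_true": arch[:, 2],
            "context_true": arch[:, 1] - arch[:, 0],
            "mir_true": arch[:, 2] - arch[:, 1],
            "context_shift": shift,
            "baseline_log2_mean": baseline,
            "category": implied_categories(arch),
        },
        index=counts_df.index,
    )
    return SimulatedExperiment(
        counts=CountMatrix(counts_df),
        sheet=SampleSheet(layout),
        truth=SyntheticTruth(truth_df),
        config=config,
    )


def stage_configs_from_modes(
    modes: pd.DataFrame,
    effect: float = 2.0,
    base_config: SimConfig | None = None,
    seed: int = 0,
) -> dict[str, SimConfig]:
    """Build per-stage configs whose implied S/N mode matrix equals ``modes``.

    ``modes`` is a gene x stage frame with entries "S"/"N".  S genes get a
    regulator-only architecture (category I), alternating the sign of c_g
    (+/-``effect``) so up- and down-regulation stay balanced and
    median-of-ratios normalization keeps an unbiased anchor; N genes are
    conserved (category V).  Stage seeds are derived from ``seed``.
    """
    if list(modes.columns) != list(STAGES):
        raise ValueError(f"modes must have columns {STAGES}")
    bad = set(np.unique(modes.to_numpy())) - {"S", "N"}
    if bad:
        raise ValueError(f"modes entries must be 'S' or 'N', got {sorted(bad)}")
    n = len(modes)
    configs = {}
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    for i, stage in enumerate(STAGES):
        arch = np.zeros((n, 3))
        s_mask = (modes[stage] == "S").to_numpy()
        arch[s_mask, 2] = effect * signs[s_mask]
        cfg = base_config if base_config is not None else SimConfig(n_genes=n)
        configs[stage] = replace(
            cfg, n_genes=n, effect_arch=arch, seed=seed + i + 1
        )
    return configs


def simulate_stage_panel(
    configs: Mapping[str, SimConfig],
    transition_spec: pd.DataFrame | None = None,
) -> dict[str, SimulatedExperiment]:
    """Simulate the four-stage panel (SG, pSC, rST, eST).

    ``configs`` maps each of the four stage names to a SimConfig.  When
    ``transition_spec`` (gene x stage, "S"/"N") is given, each stage's
    implied categories are checked against it: S stages must imply category
    I or III and N stages II, IV or V.
    """
    if sorted(configs) != sorted(STAGES):
        raise ValueError(f"stage panel requires exactly the stages {STAGES}")
    panel = {}
    for stage in STAGES:
        cfg = configs[stage]
        if transition_spec is not None:
            implied = implied_categories(np.asarray(cfg.effect_arch))
            s_mask = np.isin(implied, ("I", "III"))
            want = (transition_spec[stage] == "S").to_numpy()
            if not np.array_equal(s_mask, want):
                raise ValueError(
                    f"stage {stage}: effect architecture is inconsistent "
                    "with the transition spec"
                )
        panel[stage] = simulate_experiment(cfg, stage=stage)
    return panel


def simulate_phenotypes(
    mean_length: float,
    sd_length: float,
    n_males: int,
    sperm_per_male: int,
    seed: int = 0,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Simulate a sperm-length table: one row per measured sperm.

    Lengths are Normal(mean, sd) truncated at zero by resampling (lengths
    are physical).  Columns: genotype, male_id, sperm_id, length_mm.
    """
    if mean_length <= 0 or sd_length < 0:
        raise ValueError("mean must be positive and sd non-negative")
    if n_males < 1 or sperm_per_male < 1:
        raise ValueError("n_males and sperm_per_male must be positive")
    rng = np.random.default_rng(seed)
    total = n_males * sperm_per_male
    if sd_length == 0:
        lengths = np.full(total, mean_length)
    else:
        lengths = rng.normal(mean_length, sd_length, size=total)
        while (lengths <= 0).any():
            redo = lengths <= 0
            lengths[redo] = rng.normal(mean_length, sd_length, size=int(redo.sum()))
    return pd.DataFrame(
        {
            "genotype": genotype,
            "male_id": np.repeat(
                [f"{genotype}_m{i + 1}" for i in range(n_males)], sperm_per_male
            ),
            "sperm_id": np.tile(np.arange(1, sperm_per_male + 1), n_males),
            "length_mm": lengths,
        }
    )


def write_dataset(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated experiment in the TSV formats the readers expect.

    Produces per-species count matrices, the sample sheet, an identity
    ortholog map, the ground-truth table and the config.  Returns the path
    of each written file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    sheet = exp.sheet.table
    for species in ("mel", "sim"):
        samples = sheet.index[sheet["species"] == species]
        cm = CountMatrix(exp.counts.counts[list(samples)])
        paths[f"counts_{species}"] = outdir / f"counts_{species}.tsv"
        cm.write(paths[f"counts_{species}"])
    paths["sheet"] = outdir / "samples.tsv"
    exp.sheet.write(paths["sheet"])
    paths["orthologs"] = outdir / "orthologs.tsv"
    OrthologMap.identity(exp.counts.gene_ids).write(paths["orthologs"])
    paths["truth"] = outdir / "truth.tsv"
    exp.truth.write(paths["truth"])
    paths["config"] = outdir / "sim_config.yaml"
    exp.config.to_yaml(paths["config"])
    return paths
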
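"""Reading, validation and writing of count matrices, sample sheets, ortholog
maps and abundance matrices, plus the expression filter.

All tabular formats are TSV with a header row.  Count matrices have a first
column ``gene_id`` followed by one integer column per sample.  Sample sheets
carry the experimental design: species (``mel``/``sim``), genotype
(``WT``/``KO``/``replacement``), stage (``testis`` or one of the four
spermatogenic stages) and a replicate index.  Ortholog maps list strictly
1:1 gene pairs; the *D. melanogaster* identifier is the canonical key
throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("mel", "sim")
GENOTYPES = ("WT", "KO", "replacement")
STAGES = ("SG", "pSC", "rST", "eST")
TISSUE = "testis"
VALID_STAGES = (TISSUE,) + STAGES

#: The five (species, genotype) cells of the knockout/replacement design.
DESIGN_CELLS = (
    ("mel", "WT"),
    ("mel", "KO"),
    ("mel", "replacement"),
    ("sim", "WT"),
    ("sim", "KO"),
)

SHEET_COLUMNS = ["sample_id", "species", "genotype", "stage", "replicate"]

#: Default expression threshold: a gene counts as expressed when its mean
#: normalized count over replicates strictly exceeds this value in at least
#: one genotype.
EXPRESSION_THRESHOLD = 5.0


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix.

    ``counts`` is a DataFrame indexed by gene id with one column per sample.
    Values must be non-negative integers (floats with integral values are
    accepted and cast).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene ids")
        _check_unique(df.columns, "sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            raise ValueError("count matrix contains non-finite values")
        bad = (arr < 0) | (np.mod(arr, 1) != 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-integer or negative count {arr[g, s]!r} at gene "
                f"{df.index[g]!r}, sample {df.columns[s]!r}"
            )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def write(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name != "gene_id":
            raise ValueError(
                f"{path}: first column must be named 'gene_id', got {df.index.name!r}"
            )
        return cls(df)


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample design metadata, indexed by sample id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in SHEET_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        _check_unique(df.index, "sample ids")
        bad_sp = set(df["species"]) - set(SPECIES)
        if bad_sp:
            raise ValueError(f"unknown species: {sorted(bad_sp)}")
        bad_gt = set(df["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValueError(f"unknown genotypes: {sorted(bad_gt)}")
        bad_st = set(df["stage"]) - set(VALID_STAGES)
        if bad_st:
            raise ValueError(f"unknown stages: {sorted(bad_st)}")
        repl = df[(df["genotype"] == "replacement") & (df["species"] != "mel")]
        if len(repl):
            raise ValueError(
                "replacement genotype only exists in the mel background; "
                f"offending samples: {repl.index.tolist()}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, stage: str | None = None) -> "SampleSheet":
        if stage is None:
            return self
        return SampleSheet(self.table[self.table["stage"] == stage].copy())

    def samples_for(
        self, species: str, genotype: str, stage: str | None = None
    ) -> list[str]:
        df = self.table
        mask = (df["species"] == species) & (df["genotype"] == genotype)
        if stage is not None:
            mask &= df["stage"] == stage
        return df.index[mask].tolist()

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


@dataclass(frozen=True)
class OrthologMap:
    """Strictly 1:1 ortholog pairs (mel_gene_id, sim_gene_id).

    Identifiers appearing more than once on either side are dropped at
    construction (they are not 1:1) with a log message.
    """

    pairs: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame, compare=False)

    def __post_init__(self) -> None:
        df = self.pairs
        for col in ("mel_gene_id", "sim_gene_id"):
            if col not in df.columns:
                raise ValueError(f"ortholog map missing column {col!r}")
        dup = df["mel_gene_id"].duplicated(keep=False) | df[
            "sim_gene_id"
        ].duplicated(keep=False)
        if dup.any():
            logger.info("dropping %d non-1:1 ortholog pairs", int(dup.sum()))
            object.__setattr__(self, "dropped", df[dup].copy())
            object.__setattr__(self, "pairs", df[~dup].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.pairs)

    def write(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def identity(cls, gene_ids: Iterable[str]) -> "OrthologMap":
        ids = list(gene_ids)
        return cls(pd.DataFrame({"mel_gene_id": ids, "sim_gene_id": ids}))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of non-negative real abundances (FPKM-like)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("abundance matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("abundance matrix contains negative values")

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def read_inputs(
    count_paths: Mapping[str, str | Path],
    sheet_path: str | Path,
    ortholog_path: str | Path,
) -> tuple[dict[str, CountMatrix], SampleSheet, OrthologMap]:
    """Read and cross-validate per-species count matrices, the sample sheet
    and the ortholog map.

    ``count_paths`` maps species name ("mel"/"sim") to a count-matrix TSV.
    Every sample listed in the sheet for a species must appear in that
    species' matrix and vice versa.
    """
    sheet = SampleSheet.read(sheet_path)
    omap = OrthologMap.read(ortholog_path)
    matrices: dict[str, CountMatrix] = {}
    for species, path in count_paths.items():
        if species not in SPECIES:
            raise ValueError(f"unknown species key {species!r}")
        cm = CountMatrix.read(path)
        sheet_samples = set(
            sheet.table.index[sheet.table["species"] == species]
        )
        matrix_samples = set(cm.sample_ids)
        missing = sheet_samples - matrix_samples
        if missing:
            raise ValueError(
                f"samples in sheet but absent from the {species} count "
                f"matrix: {sorted(missing)}"
            )
        extra = matrix_samples - sheet_samples
        if extra:
            raise ValueError(
                f"samples in the {species} count matrix but absent from the "
                f"sheet: {sorted(extra)}"
            )
        matrices[species] = cm
    return matrices, sheet, omap


def map_orthologs(
    mel: CountMatrix, sim: CountMatrix, omap: OrthologMap
) -> CountMatrix:
    """Merge the two species' matrices on 1:1 ortholog pairs.

    The result has one row per pair present in both matrices, keyed by the
    mel gene id; sim columns are re-keyed accordingly.  Pairs whose gene is
    missing from either matrix are dropped with a log message.
    """
    pairs = omap.pairs
    present = pairs["mel_gene_id"].isin(mel.gene_ids) & pairs[
        "sim_gene_id"
    ].isin(sim.gene_ids)
    n_drop = int((~present).sum())
    if n_drop:
        logger.info("dropping %d ortholog pairs missing from a matrix", n_drop)
    pairs = pairs[present]
    if pairs.empty:
        raise ValueError("no ortholog pair is present in both count matrices")
    mel_part = mel.counts.loc[pairs["mel_gene_id"]]
    sim_part = sim.counts.loc[pairs["sim_gene_id"]]
    sim_part.index = pairs["mel_gene_id"].to_numpy()
    merged = pd.concat([mel_part, sim_part], axis=1)
    merged.index.name = "gene_id"
    return CountMatrix(merged)


def filter_expressed(
    merged: CountMatrix,
    sheet: SampleSheet,
    threshold: float = EXPRESSION_THRESHOLD,
    stage: str | None = None,
) -> pd.Index:
    """Return genes whose mean normalized count over replicates strictly
    exceeds ``threshold`` in at least one (species, genotype) cell.

    Normalization uses median-of-ratios size factors computed jointly over
    all samples of the analysis unit (one tissue or one stage), so the
    threshold is on a common scale across genotypes.
    """
    from . import de_engine

    sub = sheet.subset(stage)
    samples = [s for s in sub.sample_ids if s in merged.sample_ids]
    counts = merged.counts[samples]
    sf = de_engine.size_factors(counts)
    norm = counts / sf
    keep = np.zeros(len(counts), dtype=bool)
    for species, genotype in DESIGN_CELLS:
        cell = sub.samples_for(species, genotype)
        if not cell:
            continue
        keep |= (norm[cell].mean(axis=1) > threshold).to_numpy()
    retained = counts.index[keep]
    logger.info(
        "expression filter: %d of %d genes retained (threshold > %g)",
        len(retained),
        len(counts),
        threshold,
    )
    return retained


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", float_format="%.6g", index=index)
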
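"""Core data containers, tabular I/O and the sample-grouping rule.

Conventions used throughout the pipeline:

* matrices are features-in-rows, samples-in-columns (an expression matrix
  is genes x samples, a methylation matrix is CpG loci x samples);
* all tabular files are UTF-8 TSV with a header row, the first column
  holding the feature id;
* gene sets travel as GMT (set name, description, tab-separated members);
* mutation calls travel as a MAF-lite TSV with columns
  ``sample_id``, ``gene``, ``protein_change``.

Readers validate on load and raise :class:`FormatError` naming the
offending row/column rather than silently coercing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Driver genes whose carriers are removed from both arms of the comparison
#: so that the wild-type group is pan-negative.
DEFAULT_EXCLUSION_GENES = frozenset({"NRAS", "CDKN2A", "GNAQ", "KIT", "GNA11"})

MUT = "MUT"
WT = "WT"


class FormatError(ValueError):
    """A file violated the expected tabular format or a value constraint."""


def _check_unique(ids: pd.Index, what: str, path: object) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s) {dup} in {path}")


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples, non-negative RSEM-like values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene", "expression matrix")
        _check_unique(self.data.columns, "sample", "expression matrix")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            rows = self.data.index[np.isnan(values).any(axis=1)].tolist()
            raise FormatError(f"missing expression values for gene(s) {rows}")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative expression value for gene {self.data.index[i]!r} "
                f"in sample {self.data.columns[j]!r}"
            )
        self.data = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = sorted(set(gene_ids) - set(self.data.index))
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def log2_values(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(x + pseudocount) transform on the RSEM-like scale."""
        return np.log2(self.data + pseudocount)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass
class MethylationMatrix:
    """CpG methylation beta values, loci x samples, in [0, 1]; NaN = missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "locus", "methylation matrix")
        _check_unique(self.data.columns, "sample", "methylation matrix")
        values = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value {values[i, j]} outside [0, 1] at locus "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.data.loc[:, list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="locus")


@dataclass
class MutationTable:
    """MAF-lite somatic mutation records: (sample_id, gene, protein_change)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "gene", "protein_change"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise FormatError(f"mutation table missing column(s) {missing}")
        pc = self.records["protein_change"].astype(str)
        if (pc.str.strip() == "").any() or self.records["protein_change"].isna().any():
            bad = self.records.index[
                self.records["protein_change"].isna() | (pc.str.strip() == "")
            ].tolist()
            raise FormatError(f"empty protein_change at record(s) {bad}")
        self.records = self.records[required].astype(str)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class SampleGroups:
    """Per-sample mutant/wild-type labels plus excluded samples with reasons."""

    labels: dict[str, str]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.labels.items() if l not in (MUT, WT)}
        if bad:
            raise ValueError(f"labels must be {MUT!r} or {WT!r}, got {bad}")
        overlap = set(self.labels) & set(self.excluded)
        if overlap:
            raise ValueError(f"samples both labeled and excluded: {sorted(overlap)}")

    @property
    def mut_samples(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == MUT]

    @property
    def wt_samples(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == WT]

    @property
    def retained_samples(self) -> list[str]:
        return list(self.labels)

    def indicator(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean MUT mask aligned with *sample_ids* (all must be labeled)."""
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without group label: {missing}")
        return np.array([self.labels[s] == MUT for s in sample_ids], dtype=bool)

    def swapped(self) -> "SampleGroups":
        flip = {MUT: WT, WT: MUT}
        return SampleGroups({s: flip[l] for s, l in self.labels.items()}, dict(self.excluded))

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, l, "") for s, l in self.labels.items()]
        rows += [(s, "excluded", r) for s, r in self.excluded.items()]
        return pd.DataFrame(rows, columns=["sample_id", "group", "reason"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleGroups":
        labels = {}
        excluded = {}
        for _, row in frame.iterrows():
            if row["group"] == "excluded":
                excluded[str(row["sample_id"])] = str(row.get("reason", ""))
            else:
                labels[str(row["sample_id"])] = str(row["group"])
        return cls(labels, excluded)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. ChIP-Seq targets, knockdown-induced genes)."""

    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise FormatError(f"empty gene set(s): {empty}")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, members: Iterable[str]) -> None:
        members = set(members)
        if not members:
            raise FormatError(f"refusing to add empty gene set {name!r}")
        self.sets[name] = members

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_feature_matrix(path: str | Path) -> pd.DataFrame:
    try:
        # round_trip parsing keeps write/read cycles exact to the last bit
        frame = pd.read_csv(path, sep="\t", index_col=0,
                            float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    for col in frame.columns:
        if frame[col].dtype == object:
            for row, value in frame[col].items():
                if isinstance(value, str):
                    try:
                        float(value)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric value {value!r} at row "
                            f"{row!r}, column {col!r}"
                        ) from None
            frame[col] = frame[col].astype(float)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV, validating on load."""
    frame = _read_feature_matrix(path)
    _check_unique(frame.index, "gene", path)
    _check_unique(frame.columns, "sample", path)
    return ExpressionMatrix(frame)


def read_methylation_matrix(path: str | Path) -> MethylationMatrix:
    """Read a loci x samples beta-value TSV; empty cells become missing."""
    frame = _read_feature_matrix(path)
    _check_unique(frame.index, "locus", path)
    _check_unique(frame.columns, "sample", path)
    return MethylationMatrix(frame)


def read_mutation_table(path: str | Path) -> MutationTable:
    """Read a MAF-lite TSV (sample_id, gene, protein_change)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return MutationTable(frame)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; duplicate members within a set are deduplicated."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} field(s) found)"
                )
            name = fields[0]
            members = {m for m in fields[2:] if m.strip()}
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Sample grouping (pan-negative rule)
# ---------------------------------------------------------------------------

def _normalize_protein_change(change: str) -> str:
    change = change.strip()
    return change[2:] if change.startswith("p.") else change


def assign_sample_groups(
    mutations: MutationTable,
    samples: Sequence[str],
    driver_gene: str = "BRAF",
    driver_change: str = "V600E",
    exclusion_genes: frozenset[str] | set[str] = DEFAULT_EXCLUSION_GENES,
) -> SampleGroups:
    """Label samples MUT/WT under the pan-negative wild-type rule.

    A sample is MUT if it carries ``driver_gene:driver_change``; it is WT
    only if it carries no mutation in the driver gene nor in any exclusion
    gene (pan-negative). Everything else — a non-target variant of the
    driver gene, or any exclusion-gene mutation regardless of driver
    status — is excluded with the reason recorded, so that co-occurring
    driver mutations cannot confound either arm. The result does not
    depend on the order of the mutation records.
    """
    samples = list(samples)
    sample_set = set(samples)
    per_sample: dict[str, dict[str, set[str]]] = {s: {} for s in samples}
    for _, rec in mutations.records.iterrows():
        sid, gene = rec["sample_id"], rec["gene"]
        if sid not in sample_set:
            logger.warning("mutation record for unknown sample %r ignored", sid)
            continue
        change = _normalize_protein_change(rec["protein_change"])
        per_sample[sid].setdefault(gene, set()).add(change)

    target = _normalize_protein_change(driver_change)
    labels: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for sid in samples:
        muts = per_sample[sid]
        hit_exclusion = sorted(set(muts) & set(exclusion_genes))
        if hit_exclusion:
            excluded[sid] = "exclusion-gene " + ",".join(hit_exclusion)
        elif driver_gene in muts:
            if target in muts[driver_gene]:
                labels[sid] = MUT
            else:
                excluded[sid] = f"non-target {driver_gene} variant"
        else:
            labels[sid] = WT
    return SampleGroups(labels, excluded)


def intersect_samples(
    groups: SampleGroups, *matrices: ExpressionMatrix | MethylationMatrix
) -> list[str]:
    """Retained samples present in every supplied matrix, in group order."""
    keep = set(groups.retained_samples)
    for matrix in matrices:
        keep &= set(matrix.sample_ids)
    dropped = sorted(set(groups.retained_samples) - keep)
    if dropped:
        logger.info("dropping %d sample(s) absent from some matrix: %s", len(dropped), dropped)
    return [s for s in groups.retained_samples if s in keep]


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping | None = None,
) -> dict[str, str]:
    """Write one TSV per named table plus a JSON run-metadata file.

    Returns a manifest mapping table name -> written path. Empty tables
    produce header-only TSVs. Output is byte-deterministic for identical
    inputs, so reruns with the same seed and config reproduce identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest[name] = str(path)
    meta_path = out_dir / "run_metadata.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(dict(metadata or {}), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    manifest["run_metadata"] = str(meta_path)
    return manifest
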
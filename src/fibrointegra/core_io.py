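"""Domain types and tab-delimited I/O for the fibroid multi-omics pipeline.

Containers are thin wrappers around pandas objects with explicit invariants:

* :class:`BetaMatrix` — probes × samples methylation fractions in [0, 1],
  NaN marking non-detected (masked) cells.
* :class:`ProbeAnnotation` — genomic position, probe class (CpG/CpH/SNP),
  gene/TSS assignment and TFBS memberships per probe.
* :class:`CountMatrix` — genes × samples non-negative integer read counts.
* :class:`SampleSheet` — sample → patient/tissue/MED12-status metadata.
* :class:`AllelicCountTable` — per chrX locus per sample, DNA and RNA
  ref/alt read counts for X-inactivation clonality.

Coordinates are 0-based half-open internally and BED-style on disk.
Beta values of exactly 0 or 1 are clipped to [eps, 1-eps] on load so that
M-values (logit of beta) stay finite; clipping never moves a value by more
than eps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig

TISSUES = ("normal_myometrium", "fibroid", "cervical_stroma")
PROBE_CLASSES = ("CpG", "CpH", "SNP")


class SchemaError(ValueError):
    """A file's header or column set does not match the documented schema."""


class DataValidationError(ValueError):
    """A value violates a container invariant (names the offending cell)."""


class CrossReferenceError(KeyError):
    """An identifier in one table is absent from the table that defines it."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise DataValidationError(f"duplicate {what}: {dups}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Methylation fractions, probes as rows, samples as columns; NaN = masked."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """True where the beta value is missing (non-detected)."""
        return self.values.isna()

    def validate(self) -> None:
        vals = self.values.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    def clipped(self, eps: float = 1e-3) -> "BetaMatrix":
        """Clip to [eps, 1-eps] so logit transforms are finite; NaN preserved."""
        return BetaMatrix(self.values.clip(lower=eps, upper=1.0 - eps))

    def mvalues(self, eps: float = 1e-3) -> pd.DataFrame:
        b = self.values.clip(lower=eps, upper=1.0 - eps)
        return np.log2(b / (1.0 - b))

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])


@dataclass
class ProbeAnnotation:
    """Probe genomic annotation; index = probe_id.

    Columns: ``chrom``, ``pos`` (0-based), ``probe_class`` (CpG/CpH/SNP),
    ``gene`` (symbol or None), ``tss_distance`` (signed bp to the assigned
    TSS, NaN when unassigned), ``tfbs_sets`` (frozenset of TF labels).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe ids")

    def validate(self) -> None:
        t = self.table
        if (t["pos"] < 0).any():
            bad = t.index[t["pos"] < 0][0]
            raise DataValidationError(f"negative position for probe {bad!r}")
        unknown = set(t["probe_class"]) - set(PROBE_CLASSES)
        if unknown:
            raise DataValidationError(f"unknown probe class(es): {sorted(unknown)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def of_class(self, probe_class: str) -> pd.Index:
        return self.table.index[self.table["probe_class"] == probe_class]


@dataclass
class CountMatrix:
    """RNA-seq read counts, genes as rows, samples as columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise DataValidationError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class SampleSheet:
    """Sample metadata; index = sample_id.

    Columns: ``patient_id``, ``tissue``, ``med12_mutation`` (bool),
    ``med12_descriptor`` (str or None), ``race`` (str or None).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")

    def validate(self) -> None:
        unknown = set(self.table["tissue"]) - set(TISSUES)
        if unknown:
            raise DataValidationError(f"unknown tissue label(s): {sorted(unknown)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.table.index[self.table["tissue"] == tissue])

    def patient_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "patient_id"])


@dataclass
class AllelicCountTable:
    """Paired DNA/RNA allelic counts at heterozygous-candidate loci.

    One row per (locus_id, sample_id); columns ``chrom``, ``pos``,
    ``dna_ref``, ``dna_alt``, ``rna_ref``, ``rna_alt``.
    """

    table: pd.DataFrame

    def validate(self) -> None:
        t = self.table
        for col in ("dna_ref", "dna_alt", "rna_ref", "rna_alt"):
            if (t[col] < 0).any():
                raise DataValidationError(f"negative {col} count")
        if t.duplicated(subset=["locus_id", "sample_id"]).any():
            dup = t[t.duplicated(subset=["locus_id", "sample_id"])].iloc[0]
            raise DataValidationError(
                f"duplicate (locus, sample) pair: ({dup['locus_id']}, {dup['sample_id']})"
            )

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.table[self.table["sample_id"] == sample_id].set_index("locus_id")


@dataclass
class Dataset:
    """The cross-validated input bundle for one cohort."""

    beta: BetaMatrix
    annotation: ProbeAnnotation
    counts: CountMatrix
    samples: SampleSheet
    allelic: AllelicCountTable
    config: PipelineConfig = field(default_factory=PipelineConfig)


# ---------------------------------------------------------------------------
# generic table I/O (seed/threshold provenance in '#' header comments)
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    index_label: str | None = None,
    seed: int | None = None,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a TSV with deterministic column order and provenance comments.

    Floats are written with 12 significant digits so that a reload agrees to
    1e-12 relative; integers round-trip exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}={val}")
    buf = io.StringIO()
    df.to_csv(
        buf, sep="\t", float_format="%.12g",
        index=index_label is not None, index_label=index_label,
    )
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        fh.write(buf.getvalue())


def read_table(path: str | Path, *, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_header_comments(path: str | Path) -> dict[str, str]:
    """Parse '# key=value' provenance comments at the top of a written table."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                out[key.strip()] = val.strip()
    return out


def write_bedgraph(
    track: pd.DataFrame, path: str | Path, value_col: str,
    *, seed: int | None = None,
) -> None:
    """Write a 4-column bedGraph-style file (chrom, start, end, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for _, row in track.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row[value_col]:.6g}\n"
            )


# ---------------------------------------------------------------------------
# typed readers/writers
# ---------------------------------------------------------------------------

_BETA_INDEX = "probe_id"
_COUNT_INDEX = "gene_id"
_SHEET_COLUMNS = ["patient_id", "tissue", "med12_mutation", "med12_descriptor", "race"]
_ALLELIC_COLUMNS = [
    "locus_id", "chrom", "pos", "sample_id",
    "dna_ref", "dna_alt", "rna_ref", "rna_alt",
]
_ANNOT_BED_COLUMNS = [
    "chrom", "start", "end", "probe_id", "probe_class",
    "gene", "tss_distance", "tfbs",
]


def write_beta(beta: BetaMatrix, path: str | Path, *, seed: int | None = None) -> None:
    write_table(beta.values, path, index_label=_BETA_INDEX, seed=seed)


def read_beta(path: str | Path) -> BetaMatrix:
    df = read_table(path, index_col=0)
    if df.index.name != _BETA_INDEX:
        raise SchemaError(
            f"beta matrix must have first column '{_BETA_INDEX}', got {df.index.name!r}"
        )
    return BetaMatrix(df)


def write_counts(counts: CountMatrix, path: str | Path, *, seed: int | None = None) -> None:
    write_table(counts.counts, path, index_label=_COUNT_INDEX, seed=seed)


def read_counts(path: str | Path) -> CountMatrix:
    df = read_table(path, index_col=0)
    if df.index.name != _COUNT_INDEX:
        raise SchemaError(
            f"count matrix must have first column '{_COUNT_INDEX}', got {df.index.name!r}"
        )
    return CountMatrix(df.astype(np.int64))


def write_sample_sheet(sheet: SampleSheet, path: str | Path, *, seed: int | None = None) -> None:
    write_table(sheet.table[_SHEET_COLUMNS], path, index_label="sample_id", seed=seed)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = read_table(path, index_col=0)
    missing = set(_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"sample sheet missing column(s): {sorted(missing)}")
    df["med12_mutation"] = df["med12_mutation"].astype(bool)
    df["med12_descriptor"] = df["med12_descriptor"].where(df["med12_descriptor"].notna(), None)
    df["race"] = df["race"].where(df["race"].notna(), None)
    return SampleSheet(df[_SHEET_COLUMNS])


def write_annotation(annot: ProbeAnnotation, path: str | Path, *, seed: int | None = None) -> None:
    """BED-like: chrom, start, end (=start+1), probe_id, class, gene, tss_distance, tfbs."""
    t = annot.table
    out = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["pos"].astype(int),
            "end": t["pos"].astype(int) + 1,
            "probe_id": t.index,
            "probe_class": t["probe_class"],
            "gene": [g if g else "." for g in t["gene"]],
            "tss_distance": [
                "." if pd.isna(d) else str(int(d)) for d in t["tss_distance"]
            ],
            "tfbs": [";".join(sorted(s)) if s else "." for s in t["tfbs_sets"]],
        }
    )
    write_table(out.reset_index(drop=True), path, seed=seed)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = read_table(path)
    missing = set(_ANNOT_BED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"probe annotation missing column(s): {sorted(missing)}")
    table = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).to_numpy(),
            "pos": df["start"].astype(int).to_numpy(),
            "probe_class": df["probe_class"].astype(str).to_numpy(),
            "gene": [None if g in (".", "") or pd.isna(g) else str(g) for g in df["gene"]],
            "tss_distance": [
                np.nan if d in (".", "") or pd.isna(d) else float(d)
                for d in df["tss_distance"]
            ],
            "tfbs_sets": [
                frozenset() if s in (".", "") or pd.isna(s) else frozenset(str(s).split(";"))
                for s in df["tfbs"]
            ],
        },
        index=pd.Index(df["probe_id"].astype(str), name="probe_id"),
    )
    return ProbeAnnotation(table)


def write_allelic(allelic: AllelicCountTable, path: str | Path, *, seed: int | None = None) -> None:
    write_table(allelic.table[_ALLELIC_COLUMNS].reset_index(drop=True), path, seed=seed)


def read_allelic(path: str | Path) -> AllelicCountTable:
    df = read_table(path)
    missing = set(_ALLELIC_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"allelic count table missing column(s): {sorted(missing)}")
    for col in ("dna_ref", "dna_alt", "rna_ref", "rna_alt", "pos"):
        df[col] = df[col].astype(np.int64)
    return AllelicCountTable(df[_ALLELIC_COLUMNS])


def allelic_from_vcf(path: str | Path, sample_ids: list[str] | None = None) -> AllelicCountTable:
    """Build an allelic count table from a VCF with per-sample AD fields.

    DNA depths come from the AD field; RNA counts must be supplied separately
    (a VCF normally carries one assay), so rna_ref/rna_alt are zero-filled
    and expected to be merged in by the caller.
    """
    import pysam  # optional dependency, imported lazily

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        names = sample_ids or list(vcf.header.samples)
        for rec in vcf:
            locus = rec.id or f"{rec.chrom}:{rec.pos}"
            for name in names:
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) < 2:
                    continue
                rows.append(
                    {
                        "locus_id": locus,
                        "chrom": rec.chrom,
                        "pos": rec.pos - 1,  # VCF is 1-based
                        "sample_id": name,
                        "dna_ref": int(ad[0]),
                        "dna_alt": int(ad[1]),
                        "rna_ref": 0,
                        "rna_alt": 0,
                    }
                )
    return AllelicCountTable(pd.DataFrame(rows, columns=_ALLELIC_COLUMNS))


# ---------------------------------------------------------------------------
# bundle loading with cross-validation
# ---------------------------------------------------------------------------

def load_dataset(
    paths: Mapping[str, str | Path], config: PipelineConfig | None = None
) -> Dataset:
    """Load and cross-validate the five cohort files.

    ``paths`` must provide keys ``beta``, ``annotation``, ``counts``,
    ``samples`` and ``allelic``. Beta values are bounds-checked and then
    clipped to [eps, 1-eps] with eps = config.beta_clip_eps.
    """
    config = config or PipelineConfig()
    config.validate()
    required = {"beta", "annotation", "counts", "samples", "allelic"}
    missing = required - set(paths)
    if missing:
        raise SchemaError(f"load_dataset missing path(s): {sorted(missing)}")

    beta = read_beta(paths["beta"])
    annotation = read_annotation(paths["annotation"])
    counts = read_counts(paths["counts"])
    samples = read_sample_sheet(paths["samples"])
    allelic = read_allelic(paths["allelic"])

    beta.validate()
    annotation.validate()
    counts.validate()
    samples.validate()
    allelic.validate()

    known = set(samples.sample_ids)
    for what, ids in (
        ("beta matrix", beta.sample_ids),
        ("count matrix", counts.sample_ids),
        ("allelic table", allelic.table["sample_id"].unique()),
    ):
        unknown = set(ids) - known
        if unknown:
            raise CrossReferenceError(
                f"sample(s) in {what} absent from sample sheet: {sorted(unknown)[:5]}"
            )
    unannotated = set(beta.probe_ids) - set(annotation.probe_ids)
    if unannotated:
        raise CrossReferenceError(
            f"probe(s) in beta matrix absent from annotation: {sorted(unannotated)[:5]}"
        )

    return Dataset(
        beta=beta.clipped(config.beta_clip_eps),
        annotation=annotation,
        counts=counts,
        samples=samples,
        allelic=allelic,
        config=config,
    )


def write_dataset(ds: Dataset, out_dir: str | Path, *, seed: int | None = None) -> dict[str, Path]:
    """Write the five cohort files; returns the path map accepted by load_dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "annotation": out / "probe_annotation.bed",
        "counts": out / "counts.tsv",
        "samples": out / "sample_sheet.tsv",
        "allelic": out / "allelic_counts.tsv",
    }
    write_beta(ds.beta, paths["beta"], seed=seed)
    write_annotation(ds.annotation, paths["annotation"], seed=seed)
    write_counts(ds.counts, paths["counts"], seed=seed)
    write_sample_sheet(ds.samples, paths["samples"], seed=seed)
    write_allelic(ds.allelic, paths["allelic"], seed=seed)
    return paths
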
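"""Shared plumbing for the analysis drivers."""

from pathlib import Path

from fibrointegra import Dataset, PipelineConfig, TruthBundle, load_dataset

FILES = {
    "beta": "beta.tsv",
    "annotation": "probe_annotation.bed",
    "counts": "counts.tsv",
    "samples": "sample_sheet.tsv",
    "allelic": "allelic_counts.tsv",
}


def load_cohort(cohort_dir: Path) -> tuple[Dataset, TruthBundle, PipelineConfig]:
    cfg = PipelineConfig.from_yaml(cohort_dir / "config.yaml")
    ds = load_dataset({k: cohort_dir / v for k, v in FILES.items()}, cfg)
    truth = TruthBundle.from_json(cohort_dir / "truth.json")
    return ds, truth, cfg
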
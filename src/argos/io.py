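"""File formats, pipeline configuration and the end-to-end runner.

Tables are tab-separated UTF-8 with a mandatory header, "." decimals and
no quoting.  Count matrices are also accepted in GCT 1.2 (two header
lines, then Name/Description columns; Description is discarded).
Copy-number tables follow the gene-level "byGene" dialect: a gene
identifier column, optional extra annotation columns (symbol, locus),
then one column per sample of log2 ratios.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compensation import InferenceConfig, classify_compensation, fit_cohort
from .integrate import call_argos, rank_complexes
from .preprocess import classify_frequently_amplified, compute_size_factors, encode_copy_number
from .toxicity import compute_barcode_lfc, fit_toxicity_table

logger = logging.getLogger(__name__)

#: annotation column names tolerated in copy-number tables
_CN_ANNOTATION_COLUMNS = {"symbol", "gene_symbol", "locus", "locus_id", "cytoband", "description"}


def _check_unique(values: pd.Index, what: str, path) -> None:
    if values.duplicated().any():
        dup = values[values.duplicated()][0]
        raise ValueError(f"{path}: duplicate {what} {dup!r}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix (TSV or GCT 1.2)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2)
        if df.columns[0].lower() != "name":
            raise ValueError(f"{path}: GCT body must start with Name/Description")
        df = df.drop(columns=df.columns[1]).rename(columns={df.columns[0]: "gene"})
    else:
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={df.columns[0]: "gene"})
    _check_unique(pd.Index(df["gene"]), "gene id", path)
    _check_unique(df.columns[1:], "sample id", path)
    mat = df.set_index("gene")
    arr = mat.to_numpy()
    try:
        as_float = arr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric count entry ({exc})") from None
    if not np.isfinite(as_float).all():
        bad = np.argwhere(~np.isfinite(as_float))[0]
        raise ValueError(
            f"{path}: non-finite count at gene {mat.index[bad[0]]!r}, "
            f"sample {mat.columns[bad[1]]!r}"
        )
    if (as_float != np.round(as_float)).any():
        bad = np.argwhere(as_float != np.round(as_float))[0]
        raise ValueError(
            f"{path}: non-integer count at gene {mat.index[bad[0]]!r}, "
            f"sample {mat.columns[bad[1]]!r}"
        )
    mat = mat.astype(np.int64)
    mat.index.name = "gene"
    return mat


def read_copy_number(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample log2 copy-ratio table (byGene-style TSV).

    Extra leading annotation columns are detached and kept under
    ``df.attrs["annotations"]``; NaN cells are preserved (flagged missing
    by the encoder).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "gene"})
    _check_unique(pd.Index(df["gene"]), "gene id", path)
    ann_cols = [c for c in df.columns[1:] if c.lower() in _CN_ANNOTATION_COLUMNS]
    annotations = df.set_index("gene")[ann_cols] if ann_cols else None
    mat = df.set_index("gene").drop(columns=ann_cols)
    _check_unique(mat.columns, "sample id", path)
    try:
        mat = mat.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric copy-number entry ({exc})") from None
    mat.index.name = "gene"
    if annotations is not None:
        mat.attrs["annotations"] = annotations
    return mat


def read_sample_info(path: str | Path, cohort_kind: str = "cellline") -> pd.DataFrame:
    """Read per-sample metadata (sample, tissue, optional purity/wgd).

    A missing purity column defaults to 1 (cell-line behavior) with a
    prominent warning, since the tumor model reduces to the cell-line
    model at purity 1.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "sample"})
    _check_unique(pd.Index(df["sample"]), "sample id", path)
    df = df.set_index("sample")
    if "tissue" not in df.columns:
        raise ValueError(f"{path}: sample metadata needs a 'tissue' column")
    if "purity" not in df.columns:
        if cohort_kind == "tumor":
            warnings.warn(
                f"{path}: no purity column; defaulting all purities to 1 "
                "(tumor model degenerates to the cell-line model)",
                stacklevel=2,
            )
        df["purity"] = 1.0
    df["purity"] = df["purity"].fillna(1.0).astype(float)
    df["cohort_kind"] = df.get("cohort_kind", cohort_kind)
    return df


def read_orf_table(path: str | Path, pseudocount: float = 0.5) -> pd.DataFrame:
    """Read ORF-screen observations; compute lfc from counts if needed."""
    df = pd.read_csv(path, sep="\t")
    required = {"screen", "tissue", "barcode", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "lfc" not in df.columns:
        if not {"early_count", "late_count"} <= set(df.columns):
            raise ValueError(
                f"{path}: need either 'lfc' or 'early_count'+'late_count' columns"
            )
        df = compute_barcode_lfc(df, pseudocount=pseudocount)
    dup = df.duplicated(subset=["screen", "barcode"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (screen, barcode) pair at row {dup.idxmax()}")
    return df


def read_complexes(path: str | Path) -> pd.DataFrame:
    """Read complex membership (complex_id, gene; one row per membership)."""
    df = pd.read_csv(path, sep="\t")
    if not {"complex_id", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: need 'complex_id' and 'gene' columns")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


@dataclass
class CohortSpec:
    """Input files and kind of one expression/copy-number cohort."""

    name: str
    kind: str  # cellline | tumor
    counts: str
    copy_number: str
    sample_info: str


@dataclass
class PipelineConfig:
    """Everything a full ARGOS run needs, mirroring the YAML config."""

    cohorts: list[CohortSpec]
    orf: str | None = None
    complexes: str | None = None
    out_dir: str = "argos_out"
    # documented thresholds
    neutral_tolerance: float = 0.15
    amp_min_cellline: int = 3
    amp_min_tumor: int = 5
    score_threshold: float = 0.3
    toxic_growth_decrease: float = 0.30
    toxic_p: float = 1e-5
    amp_frequency: float = 0.15
    pseudocount: float = 0.5
    center_screens: bool = False
    weighted_normalizer: bool = False
    # inference
    backend: str = "mcmc"
    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        if not 0 <= self.neutral_tolerance < 1:
            raise ValueError("neutral_tolerance must lie in [0, 1)")
        for name, lo, hi in (
            ("score_threshold", 0, 2),
            ("toxic_growth_decrease", 0, 1),
            ("amp_frequency", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range [{lo}, {hi}]: {v}")
        if not 0 < self.toxic_p <= 1:
            raise ValueError("toxic_p must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohorts = [CohortSpec(**c) for c in raw.pop("cohorts")]
        return cls(cohorts=cohorts, **raw)

    def inference(self) -> InferenceConfig:
        return InferenceConfig(
            backend=self.backend,
            chains=self.chains,
            draws=self.draws,
            warmup=self.warmup,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run compensation, toxicity and integration; write the output set.

    Outputs under ``config.out_dir``: compensation.tsv (all cohorts
    stacked), toxicity.tsv, argos.tsv, complexes.tsv (when a complex
    table is given) and run_manifest.json recording the config hash,
    seed, package version and gene attrition per stage.  Deterministic
    given config + seed.

    With a single cohort the dual-cohort score thresholds are applied to
    that cohort's scores alone (provenance marked in the manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    attrition: dict[str, dict] = {}
    inference = config.inference()

    score_tables: list[pd.DataFrame] = []
    amp_tables: list[pd.Series] = []
    for cohort_spec in config.cohorts:
        counts = read_counts(cohort_spec.counts)
        cn = read_copy_number(cohort_spec.copy_number)
        meta = read_sample_info(cohort_spec.sample_info, cohort_spec.kind)
        genes = counts.index.intersection(cn.index)
        samples = counts.columns.intersection(cn.columns).intersection(meta.index)
        attrition[cohort_spec.name] = {
            "genes_counts": int(counts.shape[0]),
            "genes_copy_number": int(cn.shape[0]),
            "genes_shared": int(len(genes)),
            "samples_shared": int(len(samples)),
        }
        counts = counts.loc[genes, samples]
        cn = cn.loc[genes, samples]
        meta = meta.loc[samples].copy()
        meta["size_factor"] = compute_size_factors(counts)
        design = encode_copy_number(cn)
        min_amp = (
            config.amp_min_tumor
            if cohort_spec.kind == "tumor"
            else config.amp_min_cellline
        )
        table = fit_cohort(
            counts, design, meta, cohort_spec.kind,
            config=inference, neutral_tolerance=config.neutral_tolerance,
            min_amplified=min_amp,
            weighted_normalizer=config.weighted_normalizer,
        )
        table["cohort_name"] = cohort_spec.name
        attrition[cohort_spec.name]["genes_scored"] = int(table.shape[0])
        score_tables.append(table)
        amp = classify_frequently_amplified(design, threshold=config.amp_frequency)
        amp_tables.append(amp["frequently_amplified"])

    stacked = pd.concat([t.reset_index() for t in score_tables], ignore_index=True)
    write_table(stacked, out / "compensation.tsv", index=False)

    scores = [t.loc[t["converged"], "score"] for t in score_tables]
    if len(scores) >= 2:
        comp_class = classify_compensation(scores[0], scores[1], config.score_threshold)
        classification_mode = "dual-cohort"
    else:
        comp_class = classify_compensation(scores[0], scores[0], config.score_threshold)
        classification_mode = "single-cohort"

    amp_flags = pd.DataFrame(
        {"frequently_amplified": pd.concat(amp_tables).groupby(level=0).any()}
    )

    tox_table = None
    if config.orf:
        orf = read_orf_table(config.orf, pseudocount=config.pseudocount)
        tox_table = fit_toxicity_table(
            orf,
            scope="pan-cancer",
            growth_decrease=config.toxic_growth_decrease,
            p_threshold=config.toxic_p,
            center_screens=config.center_screens,
        )
        write_table(tox_table, out / "toxicity.tsv")

    argos_table = None
    if tox_table is not None:
        argos_table = call_argos(comp_class, tox_table, amp_flags)
        write_table(argos_table, out / "argos.tsv")
        attrition["integration"] = {
            "genes_compensation": int(comp_class.shape[0]),
            "genes_toxicity": int(tox_table.shape[0]),
            "genes_intersection": int(argos_table.shape[0]),
            "argos_calls": int(argos_table["argos"].sum()),
        }

    if config.complexes and argos_table is not None:
        complexes = read_complexes(config.complexes)
        compensated = set(argos_table.index[argos_table["compensated"]])
        universe = set(argos_table.index)
        ranked = rank_complexes(
            complexes, compensated, universe,
            toxicity_estimates=argos_table["toxicity_lfc"],
        )
        write_table(ranked, out / "complexes.tsv")

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "backend": config.backend,
        "classification_mode": classification_mode,
        "attrition": attrition,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
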
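"""Synthetic cohorts with known ground truth for parameter recovery.

Emulates the statistical structure the compensation and toxicity analyses
assume: per-tissue baseline expression, NB-distributed counts with
log-normal library-size factors, a configurable fraction of samples
carrying a one-copy gain, Beta-distributed tumor purity diluting the
cancer-cell signal with a non-cancer expression compartment, and
Gaussian per-barcode log2 fold-change noise in ORF screens.

The generative compensation parameter ``true_score`` mirrors the model's
normalized deviation coefficient: the noiseless cancer-cell mean is
``base_mean * (c + true_score * d)``, so -1 leaves expression unchanged
by a gain (full compensation), 0 scales expression with dosage, and +1
doubles the per-copy increment (full hyperactivation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TrueGeneParams:
    """Ground-truth generative parameters for one gene."""

    gene_id: str
    base_mean_by_tissue: dict[str, float]
    true_score: float = 0.0
    amp_fraction: float = 0.25
    amp_copies: float = 2.0
    nb_shape: float = 10.0
    normal_mean: float | None = None  # tumor non-cancer compartment; None -> base mean
    true_toxicity_lfc: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.base_mean_by_tissue.values()):
            raise ValueError(f"{self.gene_id}: base means must be positive")
        if self.nb_shape <= 0:
            raise ValueError(f"{self.gene_id}: nb_shape must be positive")
        if not 0.0 <= self.amp_fraction <= 1.0:
            raise ValueError(f"{self.gene_id}: amp_fraction must lie in [0, 1]")
        if self.amp_copies <= 0:
            raise ValueError(f"{self.gene_id}: amp_copies must be positive")
        if self.normal_mean is not None and self.normal_mean < 0:
            raise ValueError(f"{self.gene_id}: normal_mean must be nonnegative")

    def normal_mean_for(self, tissue: str) -> float:
        if self.normal_mean is not None:
            return self.normal_mean
        return self.base_mean_by_tissue[tissue]


@dataclass
class SimulationConfig:
    """Shape and noise parameters of a simulated study."""

    n_tissues: int = 1
    samples_per_tissue: int = 200
    cohort_kind: str = "cellline"  # or "tumor"
    purity_alpha: float = 6.0
    purity_beta: float = 3.0
    library_log_mean: float = 0.0
    library_log_sd: float = 0.3
    seed: int = 0
    n_screens: int = 3
    barcodes_per_gene: int = 2
    lfc_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_tissues < 1 or self.samples_per_tissue < 1:
            raise ValueError("n_tissues and samples_per_tissue must be >= 1")
        if self.cohort_kind not in ("cellline", "tumor"):
            raise ValueError(f"unknown cohort kind {self.cohort_kind!r}")
        if self.purity_alpha <= 0 or self.purity_beta <= 0:
            raise ValueError("Beta purity parameters must be positive")
        if self.library_log_sd < 0 or self.lfc_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


@dataclass
class SyntheticCohort:
    """A generated cohort plus the truth that produced it."""

    counts: pd.DataFrame
    log2_copy: pd.DataFrame
    sample_info: pd.DataFrame
    truth: list[TrueGeneParams]
    expected_mean: pd.DataFrame = field(repr=False, default=None)
    orf: pd.DataFrame | None = field(default=None, repr=False)
    config: SimulationConfig | None = field(default=None, repr=False)


def cancer_cell_mean(base_mean: float, c: float, true_score: float) -> float:
    """Noiseless cancer-cell expression mean at linear copy ratio ``c``."""
    d = c - 1.0
    return base_mean * (c + true_score * d)


def observed_mean(
    base_mean: float,
    c: float,
    true_score: float,
    purity: float,
    normal_mean: float,
    library_factor: float,
) -> float:
    """Noiseless observed NB mean: purity mixture scaled by library size."""
    cancer = cancer_cell_mean(base_mean, c, true_score)
    return library_factor * (purity * cancer + (1.0 - purity) * normal_mean)


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    """NB draws under the variance = mu + mu^2/shape convention."""
    mean = np.asarray(mean, dtype=float)
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def simulate_cohort(
    config: SimulationConfig, truth: list[TrueGeneParams]
) -> SyntheticCohort:
    """Generate counts, copy numbers and sample metadata with known truth.

    Per tissue, the first ``floor(amp_fraction * n)`` samples after a
    seeded shuffle carry ``log2(amp_copies)``; the rest are copy-neutral.
    Counts are NB with mean ``L * (p * cancer + (1 - p) * normal)`` and
    the gene's shape.  Cell lines have purity 1.

    Raises
    ------
    ValueError
        If a gene's true score implies a negative cancer-cell mean in any
        sample (possible when ``true_score < -c/d``).
    """
    tissues = config.tissues
    for g in truth:
        missing = [t for t in tissues if t not in g.base_mean_by_tissue]
        if missing:
            raise ValueError(f"{g.gene_id}: no base mean for tissues {missing}")

    rng = np.random.default_rng(config.seed)
    n_t = config.samples_per_tissue
    sample_ids, sample_tissue = [], []
    for t in tissues:
        for i in range(n_t):
            sample_ids.append(f"{t}_s{i + 1:04d}")
            sample_tissue.append(t)
    n_samples = len(sample_ids)

    if config.cohort_kind == "tumor":
        purity = rng.beta(config.purity_alpha, config.purity_beta, size=n_samples)
        purity = np.clip(purity, np.nextafter(0.0, 1.0), 1.0)
    else:
        purity = np.ones(n_samples)
    library = rng.lognormal(
        config.library_log_mean, config.library_log_sd, size=n_samples
    )

    genes = [g.gene_id for g in truth]
    log2_copy = np.zeros((len(genes), n_samples))
    mean_mat = np.zeros_like(log2_copy)
    counts = np.zeros(log2_copy.shape, dtype=np.int64)
    tissue_arr = np.array(sample_tissue)

    for gi, g in enumerate(truth):
        amp_mask = np.zeros(n_samples, dtype=bool)
        for t in tissues:
            idx = np.flatnonzero(tissue_arr == t)
            n_amp = int(np.floor(g.amp_fraction * len(idx)))
            order = rng.permutation(idx)
            amp_mask[order[:n_amp]] = True
        c = np.where(amp_mask, g.amp_copies, 1.0)
        log2_copy[gi] = np.log2(c)
        base = np.array([g.base_mean_by_tissue[t] for t in tissue_arr])
        cancer = base * (c + g.true_score * (c - 1.0))
        if (cancer < 0).any():
            raise ValueError(
                f"{g.gene_id}: true_score {g.true_score} implies a negative "
                "cancer-cell mean in amplified samples"
            )
        normal = np.array([g.normal_mean_for(t) for t in tissue_arr])
        mu = library * (purity * cancer + (1.0 - purity) * normal)
        mean_mat[gi] = mu
        counts[gi] = _draw_nb(rng, mu, g.nb_shape)

    sample_info = pd.DataFrame(
        {
            "sample": sample_ids,
            "tissue": sample_tissue,
            "purity": purity,
            "true_library_factor": library,
            "cohort_kind": config.cohort_kind,
        }
    ).set_index("sample")
    idx = pd.Index(genes, name="gene")
    cols = pd.Index(sample_ids, name="sample")
    return SyntheticCohort(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        log2_copy=pd.DataFrame(log2_copy, index=idx, columns=cols),
        sample_info=sample_info,
        truth=list(truth),
        expected_mean=pd.DataFrame(mean_mat, index=idx, columns=cols),
        config=config,
    )


def simulate_orf_screens(
    config: SimulationConfig, truth: list[TrueGeneParams]
) -> pd.DataFrame:
    """Barcode-level ORF screen log2 fold changes with Gaussian noise.

    One record per gene x barcode x screen; screens cycle through the
    configured tissue labels.  ``lfc ~ Normal(true_toxicity_lfc, sd)``.
    """
    if config.n_screens < 1 or config.barcodes_per_gene < 1:
        raise ValueError("n_screens and barcodes_per_gene must be >= 1")
    # offset keeps screen noise decoupled from the cohort count stream
    rng = np.random.default_rng(config.seed + 1_000_003)
    tissues = config.tissues
    records = []
    for s in range(config.n_screens):
        screen_id = f"screen{s + 1}"
        tissue = tissues[s % len(tissues)]
        for g in truth:
            noise = rng.normal(0.0, config.lfc_noise_sd, config.barcodes_per_gene)
            for b in range(config.barcodes_per_gene):
                records.append(
                    {
                        "screen": screen_id,
                        "tissue": tissue,
                        "barcode": f"{g.gene_id}_bc{b + 1}",
                        "gene": g.gene_id,
                        "lfc": g.true_toxicity_lfc + noise[b],
                    }
                )
    return pd.DataFrame.from_records(records)


def simulate_study(
    config: SimulationConfig, truth: list[TrueGeneParams]
) -> SyntheticCohort:
    """Cohort plus attached ORF screens, from one config and seed."""
    cohort = simulate_cohort(config, truth)
    cohort.orf = simulate_orf_screens(config, truth)
    return cohort


def truth_table(truth: list[TrueGeneParams], tissues: list[str]) -> pd.DataFrame:
    """Flatten ground truth to one row per gene x tissue."""
    rows = []
    for g in truth:
        for t in tissues:
            rows.append(
                {
                    "gene": g.gene_id,
                    "tissue": t,
                    "base_mean": g.base_mean_by_tissue[t],
                    "true_score": g.true_score,
                    "amp_fraction": g.amp_fraction,
                    "amp_copies": g.amp_copies,
                    "nb_shape": g.nb_shape,
                    "normal_mean": g.normal_mean_for(t),
                    "true_toxicity_lfc": g.true_toxicity_lfc,
                }
            )
    return pd.DataFrame(rows)


def write_fixture_set(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write a cohort in the pipeline's external input formats.

    Emits counts.tsv, copy_number.tsv (log2), sample_info.tsv, truth.tsv
    and, when screens are attached, orf.tsv, plus manifest.json listing
    the files.  All tables round-trip through the interface readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    counts = cohort.counts.copy()
    counts.insert(0, "gene", counts.index)
    counts.to_csv(directory / "counts.tsv", sep="\t", index=False)
    files["counts"] = "counts.tsv"

    cn = cohort.log2_copy.copy()
    cn.insert(0, "gene", cn.index)
    cn.to_csv(directory / "copy_number.tsv", sep="\t", index=False)
    files["copy_number"] = "copy_number.tsv"

    meta = cohort.sample_info.reset_index()
    meta.to_csv(directory / "sample_info.tsv", sep="\t", index=False)
    files["sample_info"] = "sample_info.tsv"

    tissues = sorted(cohort.sample_info["tissue"].unique())
    truth_table(cohort.truth, tissues).to_csv(
        directory / "truth.tsv", sep="\t", index=False
    )
    files["truth"] = "truth.tsv"

    if cohort.orf is not None:
        cohort.orf.to_csv(directory / "orf.tsv", sep="\t", index=False)
        files["orf"] = "orf.tsv"

    manifest = {
        "files": files,
        "n_genes": int(cohort.counts.shape[0]),
        "n_samples": int(cohort.counts.shape[1]),
        "cohort_kind": str(cohort.sample_info["cohort_kind"].iloc[0]),
        "seed": None if cohort.config is None else cohort.config.seed,
        "checksums": {
            name: hashlib.sha256((directory / name).read_bytes()).hexdigest()
            for name in files.values()
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
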
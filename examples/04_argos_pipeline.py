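"""Run the full ARGOS pipeline on a written synthetic fixture set.

Generates a small study (cohort + ORF screens + protein complexes),
writes it in the pipeline's external file formats, runs compensation,
toxicity and integration end-to-end, and prints the resulting ARGOS
calls and complex ranking.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from argos import (
    CohortSpec,
    PipelineConfig,
    SimulationConfig,
    TrueGeneParams,
    run_pipeline,
    simulate_study,
    write_fixture_set,
)

rng = np.random.default_rng(0)
truth = [
    TrueGeneParams(
        gene_id=f"null{i:02d}",
        base_mean_by_tissue={"tissue1": float(rng.uniform(100, 2000))},
    )
    for i in range(16)
]
# one planted ARGOS gene: compensated AND toxic when overexpressed
truth += [
    TrueGeneParams(gene_id="argos_gene", base_mean_by_tissue={"tissue1": 500.0},
                   true_score=-1.0, true_toxicity_lfc=-1.0),
    TrueGeneParams(gene_id="comp_only", base_mean_by_tissue={"tissue1": 500.0},
                   true_score=-1.0),
    TrueGeneParams(gene_id="toxic_only", base_mean_by_tissue={"tissue1": 500.0},
                   true_toxicity_lfc=-1.0),
]

workdir = Path(tempfile.mkdtemp())
study = simulate_study(SimulationConfig(seed=6, samples_per_tissue=100), truth)
write_fixture_set(study, workdir / "fixtures")

complexes = pd.DataFrame(
    {
        "complex_id": ["argos_complex"] * 2 + ["bystander_complex"] * 3,
        "gene": ["argos_gene", "comp_only", "null00", "null01", "null02"],
    }
)
complexes.to_csv(workdir / "fixtures" / "complexes.tsv", sep="\t", index=False)

config = PipelineConfig(
    cohorts=[
        CohortSpec(
            name="synthetic-cellline",
            kind="cellline",
            counts=str(workdir / "fixtures" / "counts.tsv"),
            copy_number=str(workdir / "fixtures" / "copy_number.tsv"),
            sample_info=str(workdir / "fixtures" / "sample_info.tsv"),
        )
    ],
    orf=str(workdir / "fixtures" / "orf.tsv"),
    complexes=str(workdir / "fixtures" / "complexes.tsv"),
    out_dir=str(workdir / "out"),
    draws=500,
    warmup=500,
    seed=1,
)
out = run_pipeline(config)

argos_table = pd.read_csv(out / "argos.tsv", sep="\t").set_index("gene")
cols = ["compensated", "toxic", "argos", "score_a", "toxicity_lfc"]
print(argos_table.loc[["argos_gene", "comp_only", "toxic_only", "null00"], cols].round(3))
print()
print(pd.read_csv(out / "complexes.tsv", sep="\t").round(4).to_string(index=False))
print()
print("argos = compensated AND toxic; the planted complex containing the")
print("ARGOS gene ranks first by compensation enrichment and member dropout.")
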
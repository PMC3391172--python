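"""Generate the synthetic study inputs under the default conditions.

Writes the developing-testis stage expression table (~14,000 transcripts x
10 replicates x 7 stages, with a -0.5 log2 X-linked downshift in the three
late stages), the contaminated tissue panel (tissue-specific sets coupled to
testis bias on a depleted-X background), annotations and the planted truth.
"""

from pathlib import Path

from msci import io_formats, synthetic_data

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthetic_data.SimulationConfig()
    stages, annot, _ = synthetic_data.simulate_stage_set(cfg, seed=SEED)
    io_formats.write_stage_expression(stages, OUT / "expression.tsv")
    io_formats.write_annotation(annot, OUT / "annotation.tsv")

    panel_cfg = synthetic_data.SimulationConfig(
        n_genes=12000, specific_fraction=0.05, sexbias_coupling=0.6,
        coupled_x_multiplier=0.1,
    )
    panel, pan_annot, truth = synthetic_data.simulate_tissue_panel(panel_cfg, seed=SEED)
    io_formats.write_tissue_panel(panel, OUT / "panel_signals.tsv", OUT / "panel_calls.tsv")
    io_formats.write_annotation(pan_annot, OUT / "panel_annotation.tsv")
    synthetic_data.write_truth(truth, OUT / "truth.tsv")

    for label, st in stages.items():
        print(f"{label}: {st.n_genes} genes x {st.n_replicates} replicates")
    print(f"panel: {len(panel.gene_ids)} genes x {len(panel.tissues)} tissues -> {OUT}")


if __name__ == "__main__":
    main()
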
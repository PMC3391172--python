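"""Chromosomal enrichment of tissue-specific sets, before and after removing
sex-biased genes.

Finding (default simulation): every contaminated somatic tissue set shows
apparently significant X depletion; after excluding testis- and ovary-biased
genes from both the sets and the genome background, no somatic tissue
remains significantly skewed — only the gonad sets keep their (planted)
X depletion/enrichment.  Sex-bias enrichment confirms the contamination.
"""

from pathlib import Path

from msci.enrichment_stats import chromosomal_enrichment, testis_bias_enrichment
from msci.io_formats import load_annotation, read_gene_tissue_panel
from msci.tissue_specificity import classify_specific, sex_bias_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = read_gene_tissue_panel(ROOT / "sim" / "panel_signals.tsv", ROOT / "sim" / "panel_calls.tsv")
    annot = load_annotation(ROOT / "sim" / "panel_annotation.tsv")
    calls = classify_specific(panel)
    sex = sex_bias_table(panel)

    before = chromosomal_enrichment(calls, annot, sex_calls=sex)
    after = chromosomal_enrichment(calls, annot, exclude_sex_biased=True, sex_calls=sex)
    before.to_csv(ROOT / "chromosomal_enrichment_all.tsv", sep="\t", index=False)
    after.to_csv(ROOT / "chromosomal_enrichment_filtered.tsv", sep="\t", index=False)

    tb = testis_bias_enrichment(calls, sex, annot)
    tb.to_csv(ROOT / "testis_bias_enrichment.tsv", sep="\t", index=False)

    show = ["tissue", "threshold", "n", "normalized_freq", "test_used", "p_value", "stars"]
    print("== all genes ==")
    print(before[show].to_string(index=False))
    print("== after removing testis-/ovary-biased genes ==")
    print(after[show].to_string(index=False))


if __name__ == "__main__":
    main()
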
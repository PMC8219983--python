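"""Codon-usage baselines: definitional cases, a hand-computed CAI oracle and
the Biopython cross-check."""

import math

import numpy as np
import pytest

from slofe.baselines import (
    CodonUsageModel,
    baseline_ratio,
    highly_expressed_reference,
    melp_score,
    milc,
    score_gene,
    split_codons,
)
from slofe.io import OperonMap

# a reference set with a clear codon preference: Lys AAA over AAG (3:1),
# Asn AAT over AAC (2:1), Phe TTT only
REFERENCE = {
    "r1": "ATGAAAAAAAAGAATTAA",  # M K K K(AAG) N(AAT)
    "r2": "ATGAAAAATAATTTTTAA",  # M K N N F
    "r3": "ATGAAAAAGAATTTTTAA",  # M K K(AAG) N F
}


class TestSplitCodons:
    def test_terminal_stop_dropped(self):
        assert split_codons("ATGAAATAA") == ["ATG", "AAA"]

    def test_internal_stop_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            codons = split_codons("ATGTAAAAATAA", "g")
        assert codons == ["ATG", "AAA"]

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            split_codons("ATGAA")


class TestCAI:
    def test_preferred_codon_gene_scores_one(self):
        """A gene built only from the reference's most-preferred codons has
        CAI exactly 1."""
        model = CodonUsageModel.from_reference(REFERENCE, "CAI")
        assert score_gene("AAAAATTTT", model) == pytest.approx(1.0)

    def test_toy_gene_matches_hand_computed_geometric_mean(self):
        """CAI of a mixed gene = geometric mean of the relative adaptiveness
        values, single-codon families excluded."""
        model = CodonUsageModel.from_reference(REFERENCE, "CAI")
        # counts: AAA=4, AAG=2 -> w(AAG)=0.5; AAT=3, AAC=0 -> w(AAC)=0.01 floor
        # gene: AAA AAG AAT (ATG excluded as a single-codon family)
        got = score_gene("ATGAAAAAGAAT", model)
        expected = (1.0 * 0.5 * 1.0) ** (1 / 3)
        assert got == pytest.approx(expected)

    def test_uniform_reference_scores_all_genes_equally(self):
        uniform = {"u1": "ATGAAAAAGTAA", "u2": "ATGAATAACTAA"}
        model = CodonUsageModel.from_reference(uniform, "CAI")
        assert score_gene("AAAAAT", model) == pytest.approx(
            score_gene("AAGAAC", model)
        )

    def test_matches_biopython_on_met_trp_free_gene(self):
        """Independent cross-check against Biopython's CodonAdaptationIndex
        on a gene without single-codon families (where conventions agree)."""
        from Bio.Seq import Seq
        from Bio.SeqUtils import CodonAdaptationIndex

        ref_seqs = [Seq(s) for s in REFERENCE.values()]
        bio = CodonAdaptationIndex(ref_seqs)
        model = CodonUsageModel.from_reference(REFERENCE, "CAI")
        gene = "AAAAAGAATTTT"
        assert score_gene(gene, model) == pytest.approx(
            bio.calculate(Seq(gene)), abs=1e-6
        )


class TestRCBSAndRCA:
    def test_rcbs_is_self_referential(self):
        """RCBS needs no external reference: a gene whose codon usage equals
        its positional-composition expectation scores ~0."""
        model = CodonUsageModel.from_reference(REFERENCE, "RCBS")
        # single repeated codon: observed freq 1, expectation 1 -> d = 0
        assert score_gene("AAAAAAAAA", model) == pytest.approx(0.0, abs=1e-9)

    def test_rca_single_codon_reference_scores_one(self):
        """A reference of one codon has usage equal to its positional
        expectation, so RCA is exactly 1."""
        model = CodonUsageModel.from_reference({"r": "AAA" * 10}, "RCA")
        assert score_gene("AAAAAA", model) == pytest.approx(1.0)

    def test_rca_overrepresented_codon_scores_higher(self):
        """Among observed codons, the one enriched relative to the positional
        base composition scores higher."""
        model = CodonUsageModel.from_reference(REFERENCE, "RCA")
        assert score_gene("AAAAAA", model) > score_gene("AAGAAG", model)


class TestMILCAndMELP:
    def test_milc_zero_distance_for_reference_like_gene(self):
        model = CodonUsageModel.from_reference(REFERENCE, "MELP")
        # gene with within-family frequencies identical to the reference
        gene = "AAA" * 4 + "AAG" * 2 + "AAT" * 3
        assert milc(gene, model.family_freq) == pytest.approx(
            -milc_correction(gene), abs=1e-9
        )

    def test_milc_distance_orders_he_like_before_unlike(self):
        """A gene written in the highly-expressed set's codons is closer (in
        MILC) to that set than a gene written in the disfavored codons."""
        cds = dict(REFERENCE)
        cds["lo"] = "ATGAAGAAGAACAACTAA"  # disfavored codons
        he = highly_expressed_reference(cds, fraction=0.4)
        assert set(he) <= set(REFERENCE)  # the 'lo' gene is never selected
        he_model = CodonUsageModel.from_reference(he, "MELP")
        hi_gene = "AAAAATAAATTT"
        lo_gene = "AAGAACAAGAAC"
        assert milc(hi_gene, he_model.family_freq) < milc(
            lo_gene, he_model.family_freq
        )

    def test_melp_score_is_finite_on_reference_genes(self):
        genome_model = CodonUsageModel.from_reference(REFERENCE, "MELP")
        he_model = CodonUsageModel.from_reference(
            highly_expressed_reference(REFERENCE, fraction=0.67), "MELP"
        )
        val = melp_score("AAAAAGAATTTTAATAAA", genome_model, he_model)
        assert val == val  # not NaN


def milc_correction(gene):
    # independent re-derivation of the small-sample correction term
    codons = split_codons(gene)
    fams = {}
    for c in codons:
        from slofe.baselines import _CODON_TABLE, _FAMILIES

        fams.setdefault(_CODON_TABLE[c], len(_FAMILIES[_CODON_TABLE[c]]))
    dof = sum(k - 1 for k in fams.values())
    return dof / len(codons)


class TestBaselineRatio:
    CDS = {
        "g1": "ATGAAAAATTAA",
        "g2": "ATGAAGAACTAA",
        "g3": "ATGAAAAAGTAA",
        "g4": "ATGAATTTTTAA",
    }

    def test_gene_order_four_genes(self):
        """Definitional: 1.0 : 0.75 : 0.5 : 0.25."""
        op = OperonMap(1, ("g1", "g2", "g3", "g4"), "+")
        assert baseline_ratio(op, "order", self.CDS) == [
            ("g1", 1.0), ("g2", 0.75), ("g3", 0.5), ("g4", 0.25)
        ]

    def test_single_gene_operon_is_one_under_every_method(self):
        op = OperonMap(1, ("g1",), "+")
        for method in ("CAI", "RCA", "MELP", "order"):
            ratios = baseline_ratio(op, method, self.CDS)
            assert len(ratios) == 1
            assert ratios[0][1] == pytest.approx(1.0)

    def test_gene_order_strictly_decreasing(self):
        op = OperonMap(1, ("g1", "g2", "g3"), "+")
        vals = [v for _, v in baseline_ratio(op, "order", self.CDS)]
        assert vals == sorted(vals, reverse=True) and len(set(vals)) == 3

    def test_scale_invariance_of_normalization(self):
        """Ratios are invariant to rescaling all gene scores (division by the
        first gene)."""
        op = OperonMap(1, ("g1", "g2", "g3"), "+")
        base = baseline_ratio(op, "CAI", self.CDS)
        assert base[0][1] == pytest.approx(1.0)

    def test_missing_cds_dropped_with_warning(self):
        op = OperonMap(1, ("g1", "missing"), "+")
        with pytest.warns(UserWarning):
            ratios = baseline_ratio(op, "order", self.CDS)
        assert [g for g, _ in ratios] == ["g1"]
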
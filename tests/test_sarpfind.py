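"""Domain-hit parsing, architecture classes, census arithmetic, alignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sarpscout import sarpfind
from sarpscout.sarpfind import (
    Architecture,
    DomainHit,
    ProteinRecord,
    census,
    classify_architecture,
    genome_prevalence,
    normalize_accession,
    pairwise_similarity,
    parse_domain_hits,
)

ROLE_PROFILE = {"HTH": "PF00486", "BTAD": "PF03704", "NB-ARC": "PF00931", "TPR": "PF13424"}


def hits_for(roles, protein_id="p1"):
    return [DomainHit(protein_id, ROLE_PROFILE[r], 1e-20, 1, 50) for r in roles]


class TestParseDomainHits:
    DOMTBL = (
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord\n"
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n"
        "Trans_reg_C          PF00486.27   77 prot1                -            280   2.1e-30  100.1   0.1   1   1   1.1e-32   1.3e-30   99.0   0.1     1    77     5    70     4    72 0.97 Transcriptional regulatory protein, C terminal\n"
        "BTAD                 PF03704.16  180 prot1                -            280   3.0e-25   80.0   0.0   1   1   2.0e-27   4.0e-25   79.0   0.0     1   180    80   240    78   244 0.95 Bacterial transcriptional activator domain\n"
        "SomeDom              PF99999.1    50 prot2                -            100   5.0e-03    9.0   0.0   1   1   1.0e-02   2.0e-02    8.0   0.0     1    50    10    60     8    62 0.80 weak hit\n"
    )

    def test_domtbl_parsing_and_accession_normalization(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        path.write_text(self.DOMTBL)
        hits = parse_domain_hits(path, evalue_cutoff=1e-5)
        assert [(h.protein_id, h.profile_id) for h in hits] == [
            ("prot1", "PF00486"),
            ("prot1", "PF03704"),
        ]
        assert hits[0].evalue == pytest.approx(1.3e-30)
        assert (hits[0].ali_from, hits[0].ali_to) == (5, 70)

    def test_evalue_cutoff_drops_weak_hits(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        path.write_text(self.DOMTBL)
        assert len(parse_domain_hits(path, evalue_cutoff=1.0)) == 3

    def test_simple_tsv_layout(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("p1\tPF00486.27\t1e-30\t5\t70\np1\tPF03704\t1e-25\t80\t240\n")
        hits = parse_domain_hits(path)
        assert [h.profile_id for h in hits] == ["PF00486", "PF03704"]

    def test_malformed_rows_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "hits.tsv"
        path.write_text("p1\tPF00486\t1e-30\t5\t70\np2\tPF03704\tnot_a_number\t1\t2\n")
        with caplog.at_level("WARNING"):
            hits = parse_domain_hits(path)
        assert len(hits) == 1
        assert "malformed" in caplog.text

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_domain_hits(path) == []

    def test_accession_normalization_idempotent(self):
        assert normalize_accession("PF00486.27") == "PF00486"
        assert normalize_accession(normalize_accession("PF00486.27")) == "PF00486"


EXPECTED_DECISION_TABLE = {
    frozenset(): Architecture.INCOMPLETE,
    frozenset({"HTH"}): Architecture.HTH_ONLY,
    frozenset({"BTAD"}): Architecture.BTAD_ONLY,
    frozenset({"NB-ARC"}): Architecture.INCOMPLETE,
    frozenset({"TPR"}): Architecture.INCOMPLETE,
    frozenset({"HTH", "BTAD"}): Architecture.SMALL,
    frozenset({"HTH", "NB-ARC"}): Architecture.HTH_ONLY,
    frozenset({"HTH", "TPR"}): Architecture.HTH_ONLY,
    frozenset({"BTAD", "NB-ARC"}): Architecture.BTAD_ONLY,
    frozenset({"BTAD", "TPR"}): Architecture.BTAD_ONLY,
    frozenset({"NB-ARC", "TPR"}): Architecture.INCOMPLETE,
    frozenset({"HTH", "BTAD", "NB-ARC"}): Architecture.LARGE,
    frozenset({"HTH", "BTAD", "TPR"}): Architecture.LARGE,
    frozenset({"HTH", "NB-ARC", "TPR"}): Architecture.HTH_ONLY,
    frozenset({"BTAD", "NB-ARC", "TPR"}): Architecture.BTAD_ONLY,
    frozenset({"HTH", "BTAD", "NB-ARC", "TPR"}): Architecture.LARGE,
}


class TestClassifyArchitecture:
    @pytest.mark.parametrize(
        "roles,expected", sorted(EXPECTED_DECISION_TABLE.items(), key=lambda kv: sorted(kv[0]))
    )
    def test_total_decision_table_over_all_16_subsets(self, roles, expected):
        assert classify_architecture(hits_for(roles)) is expected

    def test_btad_typo_alias_accepted(self):
        hits = [
            DomainHit("p", "PF00486.27", 1e-20, 1, 70),
            DomainHit("p", "PF93704.16", 1e-20, 80, 240),
        ]
        assert classify_architecture(hits) is Architecture.SMALL

    def test_unknown_profiles_ignored(self):
        hits = hits_for({"HTH", "BTAD"}) + [DomainHit("p1", "PF99999", 1e-40, 1, 9)]
        assert classify_architecture(hits) is Architecture.SMALL

    def test_partition_property(self):
        """Every subset maps to exactly one class; class counts sum to total."""
        results = [
            classify_architecture(hits_for(set(c)))
            for n in range(5)
            for c in itertools.combinations(ROLE_PROFILE, n)
        ]
        assert len(results) == 16
        assert sum(results.count(a) for a in Architecture) == 16


class TestCensus:
    def _proteins(self, spec):
        out = []
        for (order, arch), n in spec.items():
            for i in range(n):
                out.append(
                    ProteinRecord(
                        protein_id=f"{order}_{arch.value}_{i}",
                        taxon_order=order,
                        architecture=arch,
                    )
                )
        return out

    def test_order_share_worked_example(self):
        proteins = self._proteins(
            {
                ("Streptomycetales", Architecture.SMALL): 3289,
                ("Other", Architecture.LARGE): 6525 - 3289,
            }
        )
        table = census(proteins, group_by="order")
        assert table.loc["Streptomycetales", "percent_of_all"] == 50
        assert table.loc["Streptomycetales", "total"] == 3289

    def test_within_order_class_percentage(self):
        proteins = self._proteins(
            {
                ("Pseudonocardiales", Architecture.SMALL): 330,
                ("Pseudonocardiales", Architecture.LARGE): 750,
            }
        )
        table = census(proteins, group_by="order")
        assert table.loc["Pseudonocardiales", "total"] == 1080
        assert table.loc["Pseudonocardiales", "percent_small"] == 31

    def test_counts_sum_to_total_and_missing_group_bucketed(self):
        proteins = self._proteins({("A", Architecture.SMALL): 3})
        proteins.append(ProteinRecord("x", architecture=Architecture.BTAD_ONLY))
        table = census(proteins, group_by="order")
        classes = [a.value for a in Architecture]
        assert (table[classes].sum(axis=1) == table["total"]).all()
        assert table.loc["unknown", "btad_only"] == 1

    def test_genome_denominator(self):
        proteins = [
            ProteinRecord("p1", taxon_order="O", genome_id="g1",
                          architecture=Architecture.SMALL),
            ProteinRecord("p2", taxon_order="O", genome_id="g1",
                          architecture=Architecture.LARGE),
            ProteinRecord("p3", taxon_order="O", genome_id="g2",
                          architecture=Architecture.INCOMPLETE),
        ]
        table = census(proteins, group_by="order", denominator="genomes")
        assert table.loc["O", "total"] == 2
        assert table.loc["O", "sarp_positive"] == 1
        assert table.loc["O", "percent_positive"] == 50

    def test_unassigned_architecture_rejected(self):
        with pytest.raises(ValueError):
            census([ProteinRecord("p")], group_by="order")


class TestGenomePrevalence:
    @pytest.mark.parametrize(
        "positives,total,expected", [(611, 625, 98), (72, 72, 100), (0, 10, 0)]
    )
    def test_worked_examples(self, positives, total, expected):
        df = pd.DataFrame(
            {"genus": ["G"] * total, "sarp_positive": [True] * positives + [False] * (total - positives)}
        )
        assert genome_prevalence(df)["G"] == expected

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            genome_prevalence(pd.DataFrame({"genus": ["G"]}))


def brute_force_global_score(a, b, sub, gap_open=10.0, gap_extend=0.5):
    """Independent affine-gap Needleman-Wunsch (Gotoh) score oracle."""
    import numpy as np

    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1]][b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        r = pairwise_similarity("MKTAYIAKQRQISFVKSHFSR", "MKTAYIAKQRQISFVKSHFSR")
        assert (r.identity_percent, r.similarity_percent) == (100.0, 100.0)

    def test_single_positive_scoring_substitution(self):
        """L->I scores +2 in BLOSUM62: identity 80, similarity 100."""
        r = pairwise_similarity("MKLVA", "MKIVA")
        assert r.identity_percent == pytest.approx(80.0)
        assert r.similarity_percent == pytest.approx(100.0)
        assert r.alignment_length == 5

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            a = "".join(rng.choice(aas, size=30))
            b = "".join(rng.choice(aas, size=25))
            r1 = pairwise_similarity(a, b)
            r2 = pairwise_similarity(b, a)
            assert r1.identity_percent == pytest.approx(r2.identity_percent)
            assert r1.similarity_percent == pytest.approx(r2.similarity_percent)
            assert r1.identity_percent <= r1.similarity_percent <= 100.0

    def test_alignment_score_matches_independent_dp_oracle(self):
        from Bio import Align
        from Bio.Align import substitution_matrices

        sub = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = sub
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        for _ in range(4):
            a = "".join(rng.choice(aas, size=30))
            b = a[::-1]
            expected = brute_force_global_score(a, b, sub)
            assert aligner.score(a, b) == pytest.approx(expected)
            r = pairwise_similarity(a, b)
            assert 0.0 <= r.identity_percent <= r.similarity_percent <= 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity("", "MKL")


def test_census_tsv_roundtrip():
    proteins = [
        ProteinRecord("p1", taxon_order="O", architecture=Architecture.SMALL),
        ProteinRecord("p2", taxon_order="O", architecture=Architecture.LARGE),
    ]
    text = sarpfind.census_to_tsv(census(proteins, group_by="order"))
    df = pd.read_csv(__import__("io").StringIO(text), sep="\t", index_col=0)
    assert df.loc["O", "total"] == 2
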
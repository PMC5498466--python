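import numpy as np
import pytest

from tascreen import pairing
from tascreen.homology_search import FamilyAssignment
from tascreen.pairing import (
    GeneFeature,
    TAPairCandidate,
    find_ta_pairs,
    intergenic_distance,
    operon_report,
)
from tascreen.physchem import PhyschemSummary


def asn(gene_id, family, role):
    return FamilyAssignment(gene_id, family, role, None)


class TestIntergenicDistance:
    def test_gap(self, make_gene):
        assert intergenic_distance(make_gene("a", 1, 300), make_gene("b", 304, 600)) == 3

    def test_overlap(self, make_gene):
        assert intergenic_distance(make_gene("a", 1, 300), make_gene("b", 298, 600)) == -3

    def test_abutting(self, make_gene):
        assert intergenic_distance(make_gene("a", 1, 300), make_gene("b", 301, 600)) == 0

    def test_different_contigs_rejected(self, make_gene):
        a = make_gene("a", 1, 300, contig="c1")
        b = make_gene("b", 304, 600, contig="c2")
        with pytest.raises(ValueError, match="different contigs"):
            intergenic_distance(a, b)

    def test_unordered_input_rejected(self, make_gene):
        with pytest.raises(ValueError, match="order"):
            intergenic_distance(make_gene("a", 304, 600), make_gene("b", 1, 300))


class TestFindTaPairs:
    def test_codirected_overlap_pair(self, make_gene):
        feats = [make_gene("tox", 100, 400), make_gene("anti", 398, 650)]
        asns = [asn("tox", "relE", "toxin"), asn("anti", "relB", "antitoxin")]
        pairs = find_ta_pairs(feats, asns)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.toxin == "tox" and p.antitoxin == "anti"
        assert p.intergenic_nt == -3
        assert p.coupled is True
        assert p.antitoxin_upstream is False
        assert p.pair_rank == 1

    def test_opposite_strands_never_pair(self, make_gene):
        feats = [make_gene("tox", 100, 400, "+"), make_gene("anti", 398, 650, "-")]
        asns = [asn("tox", "relE", "toxin"), asn("anti", "relB", "antitoxin")]
        assert find_ta_pairs(feats, asns) == []

    def test_triplet_greedy_nearest_partner(self, make_gene):
        # antitoxin--5nt--toxin--2nt--antitoxin: toxin pairs with the 2-nt gap
        feats = [
            make_gene("a1", 100, 400),
            make_gene("tox", 406, 700),
            make_gene("a2", 703, 950),
        ]
        asns = [asn("a1", "relB", "antitoxin"), asn("tox", "relE", "toxin"),
                asn("a2", "yefM", "antitoxin")]
        pairs = find_ta_pairs(feats, asns)
        assert len(pairs) == 1
        assert pairs[0].antitoxin == "a2"
        assert pairs[0].intergenic_nt == 2

        # brute-force oracle: enumerate all legal matchings under the greedy rule
        legal = {("tox", "a1"): 5, ("tox", "a2"): 2}
        greedy_choice = min(legal, key=lambda k: legal[k])
        assert pairs[0].antitoxin == greedy_choice[1]

    def test_same_family_neighbors_never_pair(self, make_gene):
        feats = [make_gene("t1", 100, 400), make_gene("t2", 410, 700)]
        asns = [asn("t1", "relE", "toxin"), asn("t2", "relE", "toxin")]
        assert find_ta_pairs(feats, asns) == []
        # same family on both sides is impossible by role consistency, but the
        # different-family requirement also blocks a hypothetical same-family call
        asns = [asn("t1", "relE", "toxin"), asn("t2", "relE", "antitoxin")]
        assert find_ta_pairs(feats, asns) == []

    def test_max_intergenic_boundary(self, make_gene):
        asns = [asn("tox", "relE", "toxin"), asn("anti", "relB", "antitoxin")]
        at_limit = [make_gene("tox", 100, 400), make_gene("anti", 551, 800)]
        assert len(find_ta_pairs(at_limit, asns, max_intergenic_nt=150)) == 1
        beyond = [make_gene("tox", 100, 400), make_gene("anti", 552, 800)]
        assert find_ta_pairs(beyond, asns, max_intergenic_nt=150) == []

    def test_intervening_gene_blocks_pair(self, make_gene):
        feats = [
            make_gene("tox", 100, 200),
            make_gene("mid", 210, 230),
            make_gene("anti", 240, 340),
        ]
        asns = [asn("tox", "relE", "toxin"), asn("anti", "relB", "antitoxin")]
        assert find_ta_pairs(feats, asns) == []
        relaxed = find_ta_pairs(feats, asns, require_no_intervening=False)
        assert len(relaxed) == 1

    def test_unassigned_neighbors_ignored(self, make_gene):
        feats = [make_gene("tox", 100, 400), make_gene("u", 410, 700)]
        asns = [asn("tox", "relE", "toxin"),
                FamilyAssignment("u", None, "unassigned", None)]
        assert find_ta_pairs(feats, asns) == []

    def test_antitoxin_upstream_on_minus_strand(self, make_gene):
        # on the minus strand transcription runs right-to-left
        feats = [make_gene("tox", 100, 400, "-"), make_gene("anti", 404, 650, "-")]
        asns = [asn("tox", "relE", "toxin"), asn("anti", "relB", "antitoxin")]
        pairs = find_ta_pairs(feats, asns)
        assert pairs[0].antitoxin_upstream is True

    def test_matching_no_gene_in_two_pairs(self, make_gene):
        rng = np.random.default_rng(5)
        feats, asns = [], []
        pos = 1
        for i in range(40):
            length = int(rng.integers(100, 400))
            feats.append(make_gene(f"g{i}", pos, pos + length))
            role = ("toxin", "antitoxin")[i % 2]
            family = ("relE", "relB", "mazF", "mazE")[int(rng.integers(4))]
            role = "toxin" if family in ("relE", "mazF") else "antitoxin"
            asns.append(asn(f"g{i}", family, role))
            pos += length + int(rng.integers(-3, 120))
        pairs = find_ta_pairs(feats, asns)
        used = [g for p in pairs for g in (p.toxin, p.antitoxin)]
        assert len(used) == len(set(used))

    def test_reflection_invariance(self, make_gene):
        L = 10000
        feats = [
            make_gene("a1", 100, 400, "+"),
            make_gene("tox", 398, 700, "+"),
            make_gene("x", 1200, 1500, "-"),
        ]
        asns = [asn("a1", "relB", "antitoxin"), asn("tox", "relE", "toxin"),
                asn("x", "mazF", "toxin")]
        fwd = find_ta_pairs(feats, asns)

        flipped = [
            GeneFeature(f.gene_id, f.contig, L - f.end + 1, L - f.start + 1,
                        "-" if f.strand == "+" else "+", f.protein)
            for f in feats
        ]
        rev = find_ta_pairs(flipped, asns)
        assert len(fwd) == len(rev) == 1
        assert {fwd[0].toxin, fwd[0].antitoxin} == {rev[0].toxin, rev[0].antitoxin}
        assert fwd[0].intergenic_nt == rev[0].intergenic_nt
        assert fwd[0].antitoxin_upstream == rev[0].antitoxin_upstream


def _summary(gene_id, pi, length=100, mw=11000.0):
    return PhyschemSummary(gene_id, length, mw, pi, 0.0)


def _pair(**kw):
    defaults = dict(
        toxin="tox", antitoxin="anti", toxin_family="relE",
        antitoxin_family="relB", contig="chr", strand="+", intergenic_nt=-2,
        antitoxin_upstream=True, coupled=True, toxin_start=398, toxin_end=700,
        antitoxin_start=100, antitoxin_end=400, pair_rank=1,
    )
    defaults.update(kw)
    return TAPairCandidate(**defaults)


class TestOperonReport:
    def test_asymmetry_flag(self):
        report = operon_report(
            [_pair()], {"tox": _summary("tox", 9.8), "anti": _summary("anti", 4.5)})
        assert bool(report.pi_asymmetry[0]) is True

    def test_coupled_reported(self):
        report = operon_report(
            [_pair(intergenic_nt=-2)],
            {"tox": _summary("tox", 9.8), "anti": _summary("anti", 4.5)})
        assert bool(report.coupled[0]) is True

    def test_empty_pairs_header_only(self):
        report = operon_report([], {})
        assert len(report) == 0
        assert list(report.columns) == pairing.REPORT_COLUMNS

    def test_missing_physchem_names_gene(self):
        with pytest.raises(KeyError, match="anti"):
            operon_report([_pair()], {"tox": _summary("tox", 9.8)})


class TestInvariantsOfCandidate:
    def test_same_gene_rejected(self):
        with pytest.raises(ValueError):
            _pair(antitoxin="tox")

    def test_same_family_rejected(self):
        with pytest.raises(ValueError):
            _pair(antitoxin_family="relE")


class TestGenomeIO:
    def test_gff3_roundtrip(self, tmp_path, make_gene):
        feats = [
            make_gene("g1", 100, 400, "+", protein="MKVLAWYEDR"),
            make_gene("g2", 404, 650, "-", protein="MAYFLDFDER"),
        ]
        gff = tmp_path / "genes.gff3"
        faa = tmp_path / "prot.faa"
        pairing.write_genome_gff3(feats, gff)
        faa.write_text(">g1\nMKVLAWYEDR\n>g2\nMAYFLDFDER\n")
        loaded = pairing.load_genome(gff, faa)
        assert loaded == feats

    def test_tsv_loader(self, tmp_path):
        tsv = tmp_path / "genes.tsv"
        faa = tmp_path / "prot.faa"
        tsv.write_text("gene_id\tcontig\tstart\tend\tstrand\ng1\tchr\t100\t400\t+\n")
        faa.write_text(">g1\nMKVL\n")
        loaded = pairing.load_genome_tsv(tsv, faa)
        assert loaded[0].protein == "MKVL"
        assert loaded[0].start == 100

    def test_tsv_loader_missing_column(self, tmp_path):
        tsv = tmp_path / "genes.tsv"
        (tmp_path / "p.faa").write_text(">g1\nMKVL\n")
        tsv.write_text("gene_id\tcontig\tstart\tend\ng1\tchr\t100\t400\n")
        with pytest.raises(ValueError, match="strand"):
            pairing.load_genome_tsv(tsv, tmp_path / "p.faa")

    def test_pairs_gff3_track(self, tmp_path):
        out = tmp_path / "pairs.gff3"
        pairing.write_pairs_gff3([_pair()], out)
        body = out.read_text()
        assert body.startswith("##gff-version 3\n")
        assert "ID=ta_pair_1" in body
        assert "\t100\t700\t" in body  # spans both genes
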
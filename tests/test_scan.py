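import numpy as np
import pytest

from socmir import (
    GenomeRecord,
    MatureMiRNA,
    MiRNACatalog,
    ScanError,
    call_presence,
    reverse_complement,
    scan_genome,
)
from socmir.catalog import assign_family

from tests._oracles import naive_scan

QUERY = "ACGTACGTACGTACGTAC"  # 18 nt


def make_catalog(seqs):
    entries = []
    for i, s in enumerate(seqs):
        name = f"ame-miR-{i + 1}"
        entries.append(
            MatureMiRNA(name, "ame", assign_family(name), s, [name])
        )
    return MiRNACatalog(entries)


def random_contig(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestExactScan:
    def test_planted_forward_hit(self, rng):
        contig = random_contig(rng, 100)
        while QUERY in contig or reverse_complement(QUERY) in contig:
            contig = random_contig(rng, 100)
        contig = contig[:10] + QUERY + contig[28:]
        genome = GenomeRecord("g1", {"c1": contig})
        hits = scan_genome(make_catalog([QUERY]), genome)
        assert [(h.start, h.end, h.strand) for h in hits] == [(10, 28, "+")]
        assert hits[0].matched_sequence == QUERY

    def test_planted_reverse_hit(self, rng):
        contig = "T" * 5 + reverse_complement(QUERY) + "T" * 40
        genome = GenomeRecord("g1", {"c1": contig})
        hits = scan_genome(make_catalog([QUERY]), genome)
        assert [(h.start, h.strand) for h in hits] == [(5, "-")]

    def test_all_n_contig_yields_nothing(self):
        genome = GenomeRecord("g1", {"c1": "N" * 200})
        assert scan_genome(make_catalog([QUERY]), genome) == []

    def test_soft_masked_lowercase_matches(self):
        genome = GenomeRecord("g1", {"c1": "tt" + QUERY.lower() + "gg"})
        hits = scan_genome(make_catalog([QUERY]), genome)
        assert len(hits) == 1 and hits[0].start == 2

    def test_ambiguity_code_inside_window_blocks_match(self):
        broken = QUERY[:9] + "N" + QUERY[10:]
        genome = GenomeRecord("g1", {"c1": "TT" + broken + "GG"})
        assert scan_genome(make_catalog([QUERY]), genome) == []

    def test_self_overlapping_occurrences_all_reported(self):
        q = "ACACACACACACACAC"  # period 2, 16 nt
        contig = "AC" * 12  # 24 nt -> starts 0,2,4,6,8 on + strand
        genome = GenomeRecord("g1", {"c1": contig})
        hits = scan_genome(make_catalog([q]), genome)
        fwd = [h.start for h in hits if h.strand == "+"]
        assert fwd == [0, 2, 4, 6, 8]

    def test_zero_contig_genome_rejected(self):
        with pytest.raises(ScanError, match="zero contigs"):
            scan_genome(make_catalog([QUERY]), GenomeRecord("g1", {}))

    def test_mismatch_budget_must_be_below_query_length(self):
        genome = GenomeRecord("g1", {"c1": "A" * 50})
        with pytest.raises(ScanError):
            scan_genome(make_catalog([QUERY]), genome, max_mismatches=18)


class TestScanProperties:
    def test_matches_naive_scanner_on_random_inputs(self, rng):
        """Exact hit-set equality with the position-by-position oracle,
        including strand and N handling, over randomized trials."""
        for _ in range(100):
            n_queries = int(rng.integers(1, 5))
            queries = {}
            cat_seqs = []
            while len(cat_seqs) < n_queries:
                s = random_contig(rng, int(rng.integers(16, 25)))
                if s not in cat_seqs and reverse_complement(s) not in cat_seqs:
                    cat_seqs.append(s)
            cat = make_catalog(cat_seqs)
            queries = {e.name: e.sequence for e in cat}
            contig = list(random_contig(rng, int(rng.integers(50, 300))))
            # plant a query sometimes, sprinkle Ns
            if rng.random() < 0.7 and len(contig) > 30:
                q = cat_seqs[0]
                pos = int(rng.integers(0, len(contig) - len(q)))
                contig[pos : pos + len(q)] = list(q)
            for _ in range(int(rng.integers(0, 4))):
                contig[int(rng.integers(0, len(contig)))] = "N"
            contig = "".join(contig)
            genome = GenomeRecord("g", {"c": contig})
            got = {
                (h.mirna_name, h.start, h.strand)
                for h in scan_genome(cat, genome)
            }
            assert got == naive_scan(queries, contig)

    def test_mismatch_scan_matches_naive_and_is_monotone(self, rng):
        for _ in range(25):
            seqs = [random_contig(rng, 18)]
            cat = make_catalog(seqs)
            queries = {e.name: e.sequence for e in cat}
            contig = random_contig(rng, 120)
            genome = GenomeRecord("g", {"c": contig})
            prev = set()
            for k in (0, 1, 2):
                got = {
                    (h.mirna_name, h.start, h.strand)
                    for h in scan_genome(cat, genome, max_mismatches=k)
                }
                assert got == naive_scan(queries, contig, max_mismatches=k)
                assert prev <= got
                prev = got

    def test_strand_symmetry_under_contig_reversal(self, rng):
        cat = make_catalog([QUERY, random_contig(rng, 20)])
        contig = random_contig(rng, 250)
        L = len(contig)
        fwd = scan_genome(cat, GenomeRecord("g", {"c": contig}))
        rev = scan_genome(
            cat, GenomeRecord("g", {"c": reverse_complement(contig)})
        )
        flip = {"+": "-", "-": "+"}
        mapped = {
            (h.mirna_name, L - h.end, flip[h.strand]) for h in rev
        }
        assert {(h.mirna_name, h.start, h.strand) for h in fwd} == mapped


class TestCallPresence:
    def test_binarization_with_hit_counts(self, rng):
        cat = make_catalog([QUERY])
        contig = "TTTT".join([QUERY] * 7)
        hits = scan_genome(cat, GenomeRecord("g1", {"c": contig}))
        hits = [h for h in hits if h.strand == "+"]
        assert len(hits) == 7
        matrix = call_presence(hits, cat, ["g1", "g2"])
        assert matrix["ame-miR-1", "g1"] == 1
        assert matrix["ame-miR-1", "g2"] == 0
        assert matrix.cell_provenance.at["ame-miR-1", "g1"] == 7

    def test_unknown_genome_in_hit_is_consistency_error(self, rng):
        cat = make_catalog([QUERY])
        hits = scan_genome(
            cat, GenomeRecord("g1", {"c": "AA" + QUERY + "AA"})
        )
        with pytest.raises(ScanError, match="unknown genome"):
            call_presence(hits, cat, ["g2"])

    def test_presence_invariant_to_contig_split_and_order(self, rng):
        cat = make_catalog([QUERY])
        part = random_contig(rng, 60)
        g_one = GenomeRecord("g", {"c1": part + QUERY})
        g_two = GenomeRecord(
            "g", {"empty": random_contig(rng, 40), "c1": part + QUERY}
        )
        m1 = call_presence(scan_genome(cat, g_one), cat, ["g"])
        m2 = call_presence(scan_genome(cat, g_two), cat, ["g"])
        assert m1.values.equals(m2.values)
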
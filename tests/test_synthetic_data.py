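import numpy as np
import pytest
from scipy import stats
from Bio.Seq import reverse_complement

from near16s.identifiability import nearest_nonidentical_distances
from near16s.synthetic_data import (
    CommunitySpec,
    generate_community,
    simulate_mock_standard,
    simulate_st16s_reads,
)


def _flat_spec(**kw):
    defaults = dict(
        n_genera=2,
        species_per_genus=2,
        strains_per_species=2,
        copies_per_genome=3,
        gene_rates={"genus": 0.0, "species": 0.0, "strain": 0.0},
        upstream_rates={"genus": 0.0, "species": 0.0, "strain": 0.0},
        intragenomic_snp_rate=0.0,
        copy_context=False,
        seed=11,
    )
    defaults.update(kw)
    return CommunitySpec(**defaults)


class TestGenerateCommunity:
    def test_zero_rates_all_operons_identical(self):
        _, truth, _ = generate_community(_flat_spec())
        composites = {op.upstream_seq + op.gene_seq for op in truth.operons}
        assert len(composites) == 1

    def test_intragenomic_rate_binomial_expectation(self):
        # with only intragenomic SNPs active, two copies of a genome differ
        # at each upstream site w.p. 1-(1-r)^2-r^2/3; the mean pairwise count
        # over many pairs must sit within 3 sigma of the binomial expectation
        r = 0.01
        spec = _flat_spec(
            n_genera=1,
            species_per_genus=1,
            strains_per_species=1,
            copies_per_genome=30,
            intragenomic_snp_rate=r,
        )
        _, truth, _ = generate_community(spec)
        ups = [op.upstream_seq for op in truth.operons]
        L = len(ups[0])
        diffs = [
            sum(1 for x, y in zip(ups[i], ups[j]) if x != y)
            for i in range(len(ups))
            for j in range(i + 1, len(ups))
        ]
        p = 1 - (1 - r) ** 2 - (r ** 2) / 3
        sigma = np.sqrt(L * p * (1 - p))
        assert abs(np.mean(diffs) - L * p) < 3 * sigma

    def test_seed_determinism(self):
        spec = CommunitySpec(n_genera=2, species_per_genus=1, strains_per_species=1, seed=5)
        g1, t1, p1 = generate_community(spec)
        g2, t2, p2 = generate_community(
            CommunitySpec(n_genera=2, species_per_genus=1, strains_per_species=1, seed=5)
        )
        assert [g.contigs for g in g1] == [g.contigs for g in g2]
        assert [op.upstream_seq for op in t1.operons] == [op.upstream_seq for op in t2.operons]
        assert [p.sequence for p in p1.entries] == [p.sequence for p in p2.entries]

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_community(_flat_spec(intragenomic_snp_rate=0.5))

    def test_infeasible_genome_length(self):
        with pytest.raises(ValueError, match="too short"):
            generate_community(_flat_spec(genome_length=1000))

    def test_annotations_match_sequence(self):
        genomes, truth, _ = generate_community(_flat_spec(seed=3))
        ops = {op.locus_id: op for op in truth.operons}
        for genome in genomes:
            for i, feat in enumerate(genome.features):
                seq = genome.contigs[feat.contig_id][feat.start:feat.end]
                op = ops[f"{genome.assembly_id}|{feat.contig_id}|{i}"]
                expected = op.gene_seq if feat.strand == "+" else reverse_complement(op.gene_seq)
                assert seq == expected


@pytest.fixture(scope="module")
def mock8():
    return simulate_mock_standard("even8", seed=2)


class TestSimulateReads:
    def test_mean_extension_matches_inverse_p(self, mock8):
        _, truth, _ = mock8
        p = 0.01
        pairs, prov = simulate_st16s_reads(
            truth, termination_prob=p, n_pairs=10_000, error_rate=0.0, seed=4
        )
        primer_len = len(truth.st16s_primer)
        ext = prov["fragment_len"] - primer_len
        # exclude the few fragments capped by the template end
        max_len = max(len(truth.molecule(op)) for op in truth.operons)
        uncapped = ext[prov["fragment_len"] < max_len]
        assert abs(uncapped.mean() - 1 / p) / (1 / p) < 0.05

    def test_fragment_lengths_fit_geometric(self, mock8):
        _, truth, _ = mock8
        p = 0.01
        pairs, prov = simulate_st16s_reads(
            truth, termination_prob=p, n_pairs=10_000, error_rate=0.0, seed=8
        )
        ext = (prov["fragment_len"] - len(truth.st16s_primer)).to_numpy()
        # chi-square GOF against geometric(p) over decile bins
        qs = np.quantile(ext, np.linspace(0, 1, 11))
        edges = np.unique(np.round(qs).astype(int))
        observed, _ = np.histogram(ext, bins=np.append(edges, np.inf))
        cdf = lambda k: 1 - (1 - p) ** np.maximum(k, 0)
        upper = np.append(edges[1:], np.inf)
        expected = np.array(
            [cdf(b if np.isfinite(b) else 1e9) - cdf(a) for a, b in zip(edges, upper)]
        )
        expected = expected / expected.sum() * observed.sum()
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = 1 - stats.chi2.cdf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_tiny_p_runs_to_template_end(self):
        _, truth, _ = generate_community(_flat_spec(upstream_len=300))
        pairs, prov = simulate_st16s_reads(
            truth, termination_prob=1e-6, n_pairs=50, error_rate=0.0, seed=0
        )
        lengths = {
            len(truth.molecule(op)) for op in truth.operons
        }
        assert set(prov["fragment_len"]) <= lengths

    def test_errorfree_reads_trace_to_source(self, mock8):
        _, truth, _ = mock8
        pairs, prov = simulate_st16s_reads(truth, n_pairs=50, error_rate=0.0, seed=1)
        ops = truth.operon_by_locus()
        for pair, (_, row) in zip(pairs, prov.iterrows()):
            molecule = truth.molecule(ops[row["locus_id"]])
            assert molecule.startswith(pair.r1_seq)
            assert reverse_complement(molecule[: row["fragment_len"]]).startswith(
                pair.r2_seq
            )

    def test_read_determinism(self, mock8):
        _, truth, _ = mock8
        p1, _ = simulate_st16s_reads(truth, n_pairs=30, seed=9)
        p2, _ = simulate_st16s_reads(truth, n_pairs=30, seed=9)
        assert [(p.r1_seq, p.r2_seq) for p in p1] == [(p.r1_seq, p.r2_seq) for p in p2]


class TestMockStandards:
    def test_even8_abundances(self):
        _, truth, _ = simulate_mock_standard("even8", seed=0)
        assert len(truth.abundances) == 8
        assert all(a == pytest.approx(1 / 8) for a in truth.abundances.values())

    def test_first_member_six_distinct_copies(self):
        _, truth, _ = simulate_mock_standard("even8", seed=0)
        first = sorted(truth.copy_numbers)[0]
        assert truth.copy_numbers[first] == 6
        composites = {
            op.upstream_seq + op.gene_seq
            for op in truth.operons
            if op.assembly_id == first
        }
        assert len(composites) == 6

    def test_truth_table_determinism(self):
        _, t1, _ = simulate_mock_standard("even20", seed=3)
        _, t2, _ = simulate_mock_standard("even20", seed=3)
        assert t1.copy_numbers == t2.copy_numbers


class TestDivergenceMonotonicity:
    def test_nearest_distance_increases_with_upstream_rate(self):
        # higher upstream divergence -> larger nearest non-identical distance
        # of near-16S composites (three rate levels, strictly increasing)
        medians = []
        for rate in (0.01, 0.05, 0.15):
            spec = _flat_spec(
                n_genera=3,
                species_per_genus=2,
                strains_per_species=2,
                upstream_rates={"genus": rate, "species": rate / 2, "strain": rate / 10},
                seed=21,
            )
            _, truth, _ = generate_community(spec)
            comps = [op.upstream_seq[-400:] for op in truth.operons]
            res = nearest_nonidentical_distances(comps, n_queries=10, k=1, seed=0)
            firsts = [r["distances"][0] for r in res if r["distances"]]
            medians.append(np.median(firsts))
        assert medians[0] < medians[1] < medians[2]
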
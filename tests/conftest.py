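import pytest

from near16s import genome_io, identifiability, primer_regions
from near16s.synthetic_data import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def small_community():
    """A small hierarchical community: 3 genera x 2 species x 2 strains,
    3 gene copies per genome."""
    spec = CommunitySpec(
        n_genera=3,
        species_per_genus=2,
        strains_per_species=2,
        copies_per_genome=3,
        seed=7,
    )
    genomes, truth, primer_set = generate_community(spec)
    return genomes, truth, primer_set


@pytest.fixture(scope="session")
def community_loci(small_community):
    """Extracted loci + region maps + lineages for the small community."""
    genomes, truth, primer_set = small_community
    loci = []
    for genome in genomes:
        got, _ = genome_io.extract_linked_loci(genome)
        loci.extend(got)
    region_maps = {}
    for locus in loci:
        hits = primer_regions.find_primer_hits(locus.gene_seq, primer_set)
        region_maps[locus.locus_id] = primer_regions.qc_and_split(
            locus.gene_seq, hits, primer_set.names, locus_id=locus.locus_id
        )
    lineages = {aid: dict(row) for aid, row in truth.lineages.items()}
    return loci, region_maps, lineages


@pytest.fixture(scope="session")
def make_table(community_loci):
    """Callable building a composite table for a region spec string."""
    loci, region_maps, lineages = community_loci

    def _make(spec_text):
        spec = identifiability.RegionSpec.parse(spec_text)
        return identifiability.composite_table(loci, region_maps, lineages, spec)

    return _make
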
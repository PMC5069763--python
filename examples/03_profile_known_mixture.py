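"""End-to-end profiling of a known three-genome mixture.

Trains on three unrelated genomes, simulates 50,000 error-free reads at
proportions (0.6, 0.3, 0.1), runs the full pipeline (sample signature ->
sparse NNLS deconvolution -> taxonomic profile) and prints the recovered
abundances next to the truth.
"""

import numpy as np

from kmerpalette import aggregate_by_genome, train_database
from kmerpalette.simulate import CommunitySpec, simulate_reads
from kmerpalette.taxonomy import RANKS, TaxonomyTable


def lineage(strain, species, genus):
    names = ["k1", "p1", "c1", "o1", "f1", genus, species, strain]
    return tuple((f"{r[:2]}_{n}", f"{r} {n}") for r, n in zip(RANKS, names))


spec = CommunitySpec(
    genomes=(("gA", 20_000, 101), ("gB", 20_000, 102), ("gC", 20_000, 103)),
    mixture=(0.6, 0.3, 0.1),
    n_reads=50_000,
    read_length=100,
    seed=7,
)
genomes = spec.build_genomes()
tax = TaxonomyTable({g.id: lineage(g.id, g.id, g.id) for g in genomes})
db = train_database([[g] for g in genomes], [g.id for g in genomes], tax)

reads, truth = simulate_reads(spec, genomes=genomes)
profile, entries = db.profile_sample(reads, sample_id="mixture_demo")

x_hat = aggregate_by_genome(entries, len(genomes))
print("genome   truth   recovered")
for gid, xt, xh in zip(db.genome_ids, spec.mixture, x_hat):
    print(f"{gid:<8} {xt:<7.3f} {xh:.4f}")
print(f"L1 error: {np.abs(x_hat - np.array(spec.mixture)).sum():.4f}")

print("\nspecies-rank profile (percent):")
for taxid, pct in profile.at_rank("species").items():
    print(f"  {taxid:<10} {pct:6.2f}")
print(
    "\nEach recovered abundance is the solved mixture weight of that "
    "reference's palette; with error-free reads from training genomes "
    "essentially all mass sits on the reference (bin 1.0) columns."
)
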
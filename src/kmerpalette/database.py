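"""The trained reference bundle and the end-to-end profiling pipeline.

Training a database means: enumerate each reference genome's k-mers at both
k sizes, build the two common k-mer matrices, and fit the 30↔50-mer link
polynomial on the matrices' own entry pairs (falling back to the packaged
default coefficients when the training set is too small or degenerate to
fit).  Profiling a sample runs signature → deconvolution → taxonomy.

On disk a bundle is one directory: a versioned JSON manifest, the two
matrices as CSV, the taxonomy TSV and the reference FASTAs (kept so sample
profiling can rebuild the k-mer membership sets; they are not persisted
themselves).
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hypothetical import (
    DEFAULT_BINS,
    DEFAULT_POLYNOMIAL,
    AugmentedSystem,
    SimilarityPolynomial,
    assemble_system,
    fit_similarity_polynomial,
)
from .io import read_fasta, write_fasta
from .kmer_core import (
    CommonKmerMatrix,
    SequenceRecord,
    enumerate_kmers,
    pckm,
)
from .signature import count_sample_kmers, sample_vector, stack_signatures
from .solver import (
    DEFAULT_LAMBDA,
    AbundanceEntry,
    deconvolute,
    postprocess_abundances,
)
from .taxonomy import DEFAULT_DELTA, TaxonomyTable, TaxProfile, build_profile

__all__ = ["TrainedDatabase", "train_database", "save_bundle", "load_bundle"]

BUNDLE_FORMAT = 1


@dataclass
class TrainedDatabase:
    """Reference matrices, polynomial, bins and taxonomy for one genome set."""

    genome_ids: list[str]
    genomes: list[list[SequenceRecord]]
    matrices: dict[int, CommonKmerMatrix]
    polynomial: SimilarityPolynomial
    taxonomy: TaxonomyTable
    bins: tuple[float, ...] = DEFAULT_BINS
    kmer_sizes: tuple[int, int] = (30, 50)
    canonical: bool = True
    _kmer_sets: dict[int, list[frozenset]] = field(
        default_factory=dict, repr=False
    )

    @property
    def k1(self) -> int:
        return self.kmer_sizes[0]

    @property
    def k2(self) -> int:
        return self.kmer_sizes[1]

    def kmer_sets(self, k: int) -> list[frozenset]:
        """Distinct-k-mer sets per genome (built lazily, cached)."""
        if k not in self._kmer_sets:
            self._kmer_sets[k] = [
                enumerate_kmers(recs, k, canonical=self.canonical).key_set()
                for recs in self.genomes
            ]
        return self._kmer_sets[k]

    def assemble(self) -> AugmentedSystem:
        return assemble_system(
            self.matrices[self.k1],
            self.matrices[self.k2],
            p=self.polynomial,
            bins=self.bins,
        )

    def sample_signature(
        self, reads: Sequence[SequenceRecord], qmin: int | None = None
    ) -> np.ndarray:
        """Stacked [y^(k1); y^(k2)] signature of a read set."""
        reads = list(reads)
        sigs = []
        for k in self.kmer_sizes:
            ms = count_sample_kmers(
                reads, k, canonical=self.canonical, qmin=qmin
            )
            sigs.append(sample_vector(ms, self.kmer_sets(k), qmin=qmin))
        return stack_signatures(*sigs)

    def profile_sample(
        self,
        reads: Sequence[SequenceRecord],
        qmin: int | None = None,
        lam: float = DEFAULT_LAMBDA,
        prune_eps: float = 1e-4,
        mode: str = "default",
        delta: float = DEFAULT_DELTA,
        sample_id: str = "sample",
    ) -> tuple[TaxProfile, list[AbundanceEntry]]:
        """Full pipeline: signature → sparse NNLS → rank-wise profile."""
        y = self.sample_signature(reads, qmin=qmin)
        sol = deconvolute(self.assemble(), y, lam=lam)
        entries = postprocess_abundances(sol, eps=prune_eps)
        profile = build_profile(
            entries,
            self.taxonomy,
            self.matrices[self.k1],
            mode=mode,
            delta=delta,
            sample_id=sample_id,
        )
        return profile, entries


def train_database(
    genomes: Sequence[Sequence[SequenceRecord]],
    genome_ids: Sequence[str],
    taxonomy: TaxonomyTable,
    kmer_sizes: tuple[int, int] = (30, 50),
    bins: tuple[float, ...] = DEFAULT_BINS,
    canonical: bool = True,
    fit_polynomial: bool = True,
) -> TrainedDatabase:
    """Build matrices at both k sizes and fit the similarity polynomial.

    The polynomial is fitted on the off-diagonal-and-diagonal entry pairs
    (A30[i,j], A50[i,j]) of the freshly built matrices; when fitting is
    disabled or impossible (tiny or degenerate training sets) the packaged
    default coefficients are used instead.
    """
    if len(set(genome_ids)) != len(genome_ids):
        dupes = sorted({g for g in genome_ids if list(genome_ids).count(g) > 1})
        raise ValueError(f"duplicate genome ids: {dupes}")
    if kmer_sizes[0] >= kmer_sizes[1]:
        raise ValueError("kmer_sizes must be strictly increasing")
    missing = [g for g in genome_ids if g not in taxonomy.lineages]
    if missing:
        raise ValueError(f"genomes missing from taxonomy: {missing}")
    matrices: dict[int, CommonKmerMatrix] = {}
    kmer_sets: dict[int, list[frozenset]] = {}
    multis = {}
    for k in kmer_sizes:
        multis[k] = [
            enumerate_kmers(recs, k, canonical=canonical)
            for recs in genomes
        ]
        for gid, ms in zip(genome_ids, multis[k]):
            if ms.n_windows == 0:
                raise ValueError(f"genome {gid!r} has no valid {k}-mer window")
        M = len(genome_ids)
        values = np.empty((M, M))
        for i in range(M):
            for j in range(M):
                values[i, j] = pckm(multis[k][i], multis[k][j])
        matrices[k] = CommonKmerMatrix(
            k=k, genome_ids=list(genome_ids), values=values
        )
        kmer_sets[k] = [ms.key_set() for ms in multis[k]]
    poly = DEFAULT_POLYNOMIAL
    if fit_polynomial:
        pairs = np.column_stack(
            [matrices[kmer_sizes[0]].values.ravel(),
             matrices[kmer_sizes[1]].values.ravel()]
        )
        try:
            poly = fit_similarity_polynomial(pairs)
        except ValueError:
            poly = DEFAULT_POLYNOMIAL
    return TrainedDatabase(
        genome_ids=list(genome_ids),
        genomes=[list(recs) for recs in genomes],
        matrices=matrices,
        polynomial=poly,
        taxonomy=TaxonomyTable(
            lineages={g: taxonomy[g] for g in genome_ids}
        ),
        bins=tuple(bins),
        kmer_sizes=tuple(kmer_sizes),
        canonical=canonical,
        _kmer_sets=kmer_sets,
    )


def save_bundle(db: TrainedDatabase, path) -> None:
    """Write a bundle directory atomically (temp dir + rename)."""
    path = Path(path)
    tmp = Path(tempfile.mkdtemp(prefix=".bundle_", dir=path.parent or "."))
    try:
        manifest = {
            "format_version": BUNDLE_FORMAT,
            "kmer_sizes": list(db.kmer_sizes),
            "bins": list(db.bins),
            "polynomial": {
                "c3": db.polynomial.c3,
                "c2": db.polynomial.c2,
                "c1": db.polynomial.c1,
            },
            "canonical": db.canonical,
            "genome_ids": db.genome_ids,
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for k in db.kmer_sizes:
            db.matrices[k].to_csv(tmp / f"A{k}.csv")
        db.taxonomy.to_tsv(tmp / "taxonomy.tsv")
        gdir = tmp / "genomes"
        gdir.mkdir()
        for gid, recs in zip(db.genome_ids, db.genomes):
            write_fasta(recs, gdir / f"{gid}.fasta")
        if path.exists():
            shutil.rmtree(path)
        tmp.rename(path)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise


def load_bundle(path) -> TrainedDatabase:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["format_version"] != BUNDLE_FORMAT:
        raise ValueError(
            f"unsupported bundle format {manifest['format_version']}"
        )
    kmer_sizes = tuple(manifest["kmer_sizes"])
    matrices = {
        k: CommonKmerMatrix.from_csv(path / f"A{k}.csv", k=k)
        for k in kmer_sizes
    }
    genome_ids = manifest["genome_ids"]
    genomes = [read_fasta(path / "genomes" / f"{gid}.fasta") for gid in genome_ids]
    pc = manifest["polynomial"]
    return TrainedDatabase(
        genome_ids=genome_ids,
        genomes=genomes,
        matrices=matrices,
        polynomial=SimilarityPolynomial(c3=pc["c3"], c2=pc["c2"], c1=pc["c1"]),
        taxonomy=TaxonomyTable.from_tsv(path / "taxonomy.tsv"),
        bins=tuple(manifest["bins"]),
        kmer_sizes=kmer_sizes,
        canonical=manifest["canonical"],
    )
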
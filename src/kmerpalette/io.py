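"""File formats: FASTA/FASTQ (plain, gzip, bzip2), manifests, profiles.

Sequence parsing is delegated to Bio.SeqIO; compression is inferred from
the ``.gz`` / ``.bz2`` suffix.  The taxonomic profile reader/writer
implements the Bioboxes profiling format, version 0.9 (tab-separated
``@@TAXID RANK TAXPATH TAXPATHSN PERCENTAGE`` table under @-headers).
"""

from __future__ import annotations

import bz2
import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .kmer_core import SequenceRecord
from .taxonomy import RANKS, ProfileEntry, TaxProfile

__all__ = [
    "open_maybe_compressed",
    "read_fasta",
    "read_fastq",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_manifest",
    "write_profile",
    "read_profile",
]

_PROFILE_VERSION = "0.9.1"


def open_maybe_compressed(path, mode: str = "rt"):
    """Open a path, transparently decompressing by .gz/.bz2 suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    if path.suffix == ".bz2":
        return bz2.open(path, mode)
    return open(path, mode)


def _strip_compression(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in (".gz", ".bz2") else path


def _sequence_format(path) -> str:
    suffix = _strip_compression(Path(path)).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def read_fasta(path) -> list[SequenceRecord]:
    with open_maybe_compressed(path) as fh:
        return [
            SequenceRecord(id=rec.id, seq=str(rec.seq))
            for rec in SeqIO.parse(fh, "fasta")
        ]


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Yield reads with their Phred scores attached."""
    with open_maybe_compressed(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                qual=tuple(rec.letter_annotations["phred_quality"]),
            )


def read_sequences(path) -> Iterator[SequenceRecord]:
    """Read FASTA or FASTQ by suffix; FASTQ keeps qualities."""
    if _sequence_format(path) == "fastq":
        yield from read_fastq(path)
    else:
        yield from read_fasta(path)


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open_maybe_compressed(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open_maybe_compressed(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"read {rec.id!r} has no quality scores")
            qual = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_manifest(path) -> list[tuple[str, Path]]:
    """genome_id<TAB>fasta_path lines; duplicate ids are an error."""
    base = Path(path).parent
    entries: list[tuple[str, Path]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, fasta = line.split("\t")
            if gid in seen:
                raise ValueError(f"duplicate genome id in manifest: {gid!r}")
            seen.add(gid)
            p = Path(fasta)
            entries.append((gid, p if p.is_absolute() else base / p))
    return entries


def write_profile(profile: TaxProfile, path) -> None:
    """Write a Bioboxes v0.9 taxonomic profile."""
    with open(path, "w") as fh:
        fh.write(f"@SampleID:{profile.sample_id}\n")
        fh.write(f"@Version:{_PROFILE_VERSION}\n")
        fh.write("@Ranks:" + "|".join(RANKS) + "\n")
        fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
        for e in profile.entries:
            fh.write(
                f"{e.taxid}\t{e.rank}\t{e.taxpath}\t{e.taxpath_names}\t"
                f"{e.percentage:.9f}\n"
            )


def read_profile(path) -> TaxProfile:
    """Parse a Bioboxes v0.9 taxonomic profile."""
    sample_id = "sample"
    entries: list[ProfileEntry] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@SampleID:"):
                sample_id = line.split(":", 1)[1]
            elif line.startswith("@"):
                continue
            else:
                taxid, rank, taxpath, names, pct = line.split("\t")
                if rank not in RANKS:
                    raise ValueError(f"unknown rank {rank!r} in profile")
                entries.append(
                    ProfileEntry(
                        rank=rank,
                        taxid=taxid,
                        taxpath=taxpath,
                        taxpath_names=names,
                        percentage=float(pct),
                    )
                )
    return TaxProfile(entries=entries, sample_id=sample_id)
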
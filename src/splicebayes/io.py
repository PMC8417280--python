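"""Sequence I/O: paired-end FASTQ input and annotated FASTA output.

Reads are consumed as :class:`ReadPair` objects; assembled transcripts are
written as FASTA records whose headers carry the calling metadata
(graph of origin, relative abundance, posterior expression probability)
as ``key=value`` tokens.

Quality strings are parsed but discarded: downstream error handling is
k-mer-frequency based and never consults base qualities.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Malformed FASTQ record; message names the offending line number."""


class PairingError(ValueError):
    """Mate files (or interleaved stream) disagree on record counts/ids."""


@dataclass(frozen=True)
class ReadPair:
    """One paired-end fragment: two mate sequences read off its ends.

    ``mate2`` may be empty for effectively single-end records (used by some
    low-level helpers); regular pipeline input is always paired.
    """

    fragment_id: str
    mate1: str
    mate2: str = ""
    stranded: bool = True

    def __post_init__(self) -> None:
        if not self.mate1:
            raise ValueError(f"{self.fragment_id}: mate1 is empty")
        for mate in (self.mate1, self.mate2):
            if set(mate) - DNA_ALPHABET:
                bad = sorted(set(mate) - DNA_ALPHABET)
                raise ValueError(
                    f"{self.fragment_id}: non-DNA characters {bad} in read"
                )


@dataclass
class AssembledTranscript:
    """A called transcript with its provenance and posterior summaries.

    ``abundance`` is the posterior-mean relative abundance within the
    transcript's splicing graph (called transcripts of one graph sum to <= 1);
    ``posterior_expression`` is the posterior probability that the hidden
    expression indicator is on.
    """

    transcript_id: str
    sequence: str
    graph_id: str
    abundance: float
    posterior_expression: float


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fastq_records(handle: IO[str], path_label: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a 4-line FASTQ stream.

    Raises :class:`FastqFormatError` with 1-based line numbers on malformed
    records (missing '@', missing '+', seq/qual length mismatch, truncation).
    """
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise FastqFormatError(
                f"{path_label}: line {lineno}: expected '@' header, got {header[:30]!r}"
            )
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        if not qual and not plus:
            raise FastqFormatError(
                f"{path_label}: line {lineno}: truncated record"
            )
        lineno += 3
        if not plus.startswith("+"):
            raise FastqFormatError(
                f"{path_label}: line {lineno - 1}: expected '+' separator"
            )
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"{path_label}: line {lineno}: quality length {len(qual)} "
                f"!= sequence length {len(seq)}"
            )
        yield header[1:].split()[0], seq.upper()


def _strip_mate_suffix(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def read_fastq(
    path: str | Path,
    paired_path: str | Path | None = None,
    *,
    interleaved: bool = False,
    stranded: bool = True,
) -> Iterator[ReadPair]:
    """Stream :class:`ReadPair` objects from paired or interleaved FASTQ.

    Parameters
    ----------
    path
        Mate-1 FASTQ (or the single interleaved file when ``interleaved``).
    paired_path
        Mate-2 FASTQ; required unless ``interleaved`` is set.
    interleaved
        Records alternate mate1/mate2 within ``path``.
    stranded
        Propagated onto each emitted :class:`ReadPair`.
    """
    if interleaved:
        if paired_path is not None:
            raise ValueError("interleaved input takes a single file")
        with _open_text(path) as fh:
            records = _fastq_records(fh, str(path))
            for rid1, seq1 in records:
                try:
                    rid2, seq2 = next(records)
                except StopIteration:
                    raise PairingError(
                        f"{path}: odd record count in interleaved FASTQ "
                        f"(mate2 missing for {rid1!r})"
                    ) from None
                yield ReadPair(_strip_mate_suffix(rid1), seq1, seq2, stranded)
        return

    if paired_path is None:
        raise ValueError("paired_path required for two-file input")
    with _open_text(path) as fh1, _open_text(paired_path) as fh2:
        recs1 = _fastq_records(fh1, str(path))
        recs2 = _fastq_records(fh2, str(paired_path))
        for rid1, seq1 in recs1:
            try:
                _rid2, seq2 = next(recs2)
            except StopIteration:
                raise PairingError(
                    f"{paired_path}: fewer records than {path} "
                    f"(no mate for {rid1!r})"
                ) from None
            yield ReadPair(_strip_mate_suffix(rid1), seq1, seq2, stranded)
        try:
            next(recs2)
        except StopIteration:
            pass
        else:
            raise PairingError(f"{paired_path}: more records than {path}")


def write_transcripts_fasta(
    transcripts: Sequence[AssembledTranscript], path: str | Path
) -> None:
    """Write transcripts as 60-column-wrapped FASTA.

    Header: ``>transcript_id graph=<id> abundance=<x> posterior=<p>``.
    Duplicate transcript ids abort before anything is written.
    """
    seen: set[str] = set()
    for t in transcripts:
        if t.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        seen.add(t.transcript_id)
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=t.transcript_id,
            description=(
                f"graph={t.graph_id} abundance={t.abundance:.6f} "
                f"posterior={t.posterior_expression:.6f}"
            ),
        )
        for t in transcripts
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_transcripts_fasta(path: str | Path) -> list[AssembledTranscript]:
    """Inverse of :func:`write_transcripts_fasta`."""
    out: list[AssembledTranscript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        out.append(
            AssembledTranscript(
                transcript_id=rec.id,
                sequence=str(rec.seq).upper(),
                graph_id=tokens.get("graph", ""),
                abundance=float(tokens.get("abundance", "nan")),
                posterior_expression=float(tokens.get("posterior", "nan")),
            )
        )
    return out


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Plain id -> sequence mapping from a FASTA file."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta_sequences(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
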
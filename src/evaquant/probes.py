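"""Oligo probe tiling for FISH-style assays.

Tiles fixed-length probes (default 30-mers) across a target region with a
fixed inter-probe gap (default 20 bp), filters low-complexity and
non-unique probes, and appends the common 3' detection tail shared by all
oligos of a probe set.

Coordinates are 0-based half-open on the given (sense) strand throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from collections import Counter
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Common 3' detection tail appended to every gene-specific oligo.
COMMON_TAIL = "TAGTTTCAGCTTTCCGCAAC"

_VALID_BASES = set("ACGTN")
_ACGT = set("ACGT")


@dataclass(frozen=True)
class Probe:
    """A single tiled oligo: core matches the target exactly at [start, end)."""

    start: int
    end: int
    strand: str  # "+" or "-"
    core: str
    full: str  # core + tail once a tail has been appended


@dataclass
class ProbeSet:
    """An ordered, non-overlapping set of tiled probes over one target."""

    target_name: str
    region_length: int
    probes: list[Probe] = field(default_factory=list)
    tail: str = ""

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.target_name,
                "start": [p.start for p in self.probes],
                "end": [p.end for p in self.probes],
                "strand": [p.strand for p in self.probes],
                "core": [p.core for p in self.probes],
                "full": [p.full for p in self.probes],
            }
        )


def tile_probes(
    sequence: str,
    probe_len: int = 30,
    gap: int = 20,
    target_name: str = "target",
    strand: str = "+",
) -> ProbeSet:
    """Greedy left-to-right tiling at stride ``probe_len + gap`` starting at 0.

    Windows containing ``N`` are skipped but the placement stride still
    advances, so probe coordinates stay on the regular grid.  For an N-free
    sequence of length ``L >= probe_len`` the probe count is
    ``(L - probe_len) // (probe_len + gap) + 1``.
    """
    sequence = sequence.upper()
    if set(sequence) - _VALID_BASES:
        bad = sorted(set(sequence) - _VALID_BASES)
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    if probe_len < 10:
        raise ValueError(f"probe_len must be >= 10, got {probe_len}")
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")

    L = len(sequence)
    ps = ProbeSet(target_name=target_name, region_length=L)
    if L < probe_len:
        logger.warning(
            "target %s shorter than probe length (%d < %d): empty probe set",
            target_name, L, probe_len,
        )
        return ps

    stride = probe_len + gap
    for start in range(0, L - probe_len + 1, stride):
        core = sequence[start : start + probe_len]
        if "N" in core:
            continue
        ps.probes.append(Probe(start, start + probe_len, strand, core, core))
    return ps


def _dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping-dinucleotide distribution."""
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def _max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _background_kmer_counts(background: Iterable[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in background:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return counts


def filter_probes(
    ps: ProbeSet,
    background: Sequence[str] | None = None,
    entropy_min: float = 2.0,
    max_homopolymer: int = 8,
    k: int = 16,
    max_kmer_hits: int = 1,
    gc_bounds: tuple[float, float] | None = None,
) -> tuple[ProbeSet, pd.DataFrame]:
    """Remove low-complexity and repeated/non-unique probes.

    Rules (each may be disabled by passing ``None``/omitting the input):

    * complexity — drop probes whose dinucleotide Shannon entropy falls
      below ``entropy_min`` bits or that contain a homopolymer run longer
      than ``max_homopolymer``;
    * uniqueness — drop probes any of whose ``k``-mers (forward or reverse
      complement) occurs more than ``max_kmer_hits`` times across the
      supplied ``background`` sequences.  Supply a background that includes
      the target region itself so that a count above 1 signals a second
      genomic site;
    * GC — drop probes with GC fraction outside ``gc_bounds`` (off by
      default).

    Returns the filtered set and a per-probe report (status + reason).
    """
    bg_counts = _background_kmer_counts(background, k) if background else None

    kept: list[Probe] = []
    rows = []
    for p in ps.probes:
        reason = ""
        ent = _dinucleotide_entropy(p.core)
        if ent < entropy_min:
            reason = f"low_complexity:entropy={ent:.2f}<{entropy_min}"
        elif _max_homopolymer_run(p.core) > max_homopolymer:
            reason = f"low_complexity:homopolymer>{max_homopolymer}"
        elif gc_bounds is not None:
            gc = _gc_fraction(p.core)
            if not (gc_bounds[0] <= gc <= gc_bounds[1]):
                reason = f"gc_out_of_bounds:{gc:.2f}"
        if not reason and bg_counts is not None:
            for i in range(len(p.core) - k + 1):
                kmer = p.core[i : i + k]
                hits = bg_counts[kmer] + bg_counts[str(Seq(kmer).reverse_complement())]
                if hits > max_kmer_hits:
                    reason = f"non_unique:kmer@{p.start + i}x{hits}"
                    break
        if reason:
            logger.info("probe %s:%d-%d removed (%s)", ps.target_name, p.start, p.end, reason)
        else:
            kept.append(p)
        rows.append(
            {"start": p.start, "end": p.end, "kept": not reason, "reason": reason}
        )

    out = ProbeSet(ps.target_name, ps.region_length, kept, ps.tail)
    return out, pd.DataFrame(rows)


def append_common_tail(ps: ProbeSet, tail: str = COMMON_TAIL) -> ProbeSet:
    """Attach the common 3' detection sequence to every probe core."""
    tail = tail.upper()
    if not tail or set(tail) - _ACGT:
        raise ValueError(f"tail must be a nonempty ACGT string, got {tail!r}")
    probes = [replace(p, full=p.core + tail) for p in ps.probes]
    return ProbeSet(ps.target_name, ps.region_length, probes, tail)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_probes_fasta(ps: ProbeSet, path) -> None:
    """Write full oligos as FASTA with ``target|start-end`` headers."""
    records = [
        SeqRecord(Seq(p.full), id=f"{ps.target_name}|{p.start}-{p.end}", description="")
        for p in ps.probes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_probes_tsv(ps: ProbeSet, path, report: pd.DataFrame | None = None) -> None:
    """Write probe coordinates and sequences as TSV (optionally with filter status)."""
    df = ps.to_frame()
    if report is not None:
        df = df.merge(report, on=["start", "end"], how="left")
    df.to_csv(path, sep="\t", index=False)
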
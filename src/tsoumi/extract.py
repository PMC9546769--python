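"""UMI motif grammars and extraction from paired reads.

A 5' UMI read begins with the template-switching oligo (TSO) footprint:
a full or tagmentation-truncated 5' adapter, an 8-nt random UMI, an optional
fixed 5-nt spacer, and a GG anchor left by the terminal riboguanosines. Two
dialects are supported:

``spacer``
    adapter-suffix (length >= 2) + UMI + spacer + GG. The designed read-1
    configuration of spacer-bearing TSOs.
``nospacer``
    adapter-suffix (length >= 4) + UMI + GG. TSOs without a spacer.

Tagmentation can cut inside the TSO itself, which flips the motif onto the
second mate behind a very short adapter remnant (2-4 bases by default); such
pairs are rescued by the read-2 grammar and reoriented so the UMI-bearing
mate becomes read 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .io import ReadPair

DEFAULT_ADAPTER = "AAGCAGTGGTATCAACGCAGAGT"
DEFAULT_SPACER = "CTAAC"

DIALECTS = ("spacer", "nospacer")

_UMI_BASES = frozenset("ACGTN")


class OligoConfigError(ValueError):
    pass


@dataclass(frozen=True)
class OligoConfig:
    """Declarative description of the adapter/UMI/spacer/anchor motif."""

    adapter: str = DEFAULT_ADAPTER
    umi_len: int = 8
    spacer: str = DEFAULT_SPACER
    anchor: str = "GG"
    r1_min_adapter_suffix: Optional[int] = None  # None -> dialect default
    r2_adapter_suffixes: tuple[str, ...] = ("GAGT", "AGT", "GT")

    def __post_init__(self) -> None:
        if self.umi_len != 8:
            raise OligoConfigError("umi_len must be 8")
        if not self.anchor:
            raise OligoConfigError("anchor must be non-empty")
        for s in self.r2_adapter_suffixes:
            if not self.adapter.endswith(s):
                raise OligoConfigError(f"{s!r} is not a suffix of the adapter")

    def min_suffix_for(self, dialect: str) -> int:
        """Minimum accepted read-1 adapter suffix length for a dialect.

        Truncations remove N = 1..(len-2) leading bases in the spacer
        dialect and N = 1..(len-4) in the nospacer dialect; the full
        adapter is always accepted.
        """
        if self.r1_min_adapter_suffix is not None:
            return self.r1_min_adapter_suffix
        if dialect == "spacer":
            return 2
        if dialect == "nospacer":
            return 4
        raise OligoConfigError(f"unknown dialect {dialect!r}")


@dataclass
class UmiExtraction:
    """One extracted UMI with its trimmed, reoriented read pair."""

    read_id: str
    umi: str
    source: str  # 'R1' or 'R2'
    matched_adapter_suffix_len: int
    pair: ReadPair  # motif removed from mate 1; mates swapped when source=R2


class MotifMatcher:
    """Matches adapter-suffix + UMI + spacer + anchor at the read 5' end.

    Suffix lengths are tried longest-first so the reported suffix length is
    maximal; adapter, spacer and anchor matching is exact.
    """

    def __init__(self, adapter: str, umi_len: int, spacer: str, anchor: str,
                 suffix_lengths: Sequence[int]):
        self.umi_len = umi_len
        self.spacer = spacer
        self.anchor = anchor
        self._suffixes = [(L, adapter[len(adapter) - L:])
                          for L in sorted(set(suffix_lengths), reverse=True)]
        self.tail = len(spacer) + len(anchor)

    def match(self, seq: str) -> Optional[tuple[int, str, int]]:
        """Return (suffix_len, umi, motif_len) for a matching read, else None."""
        for L, suffix in self._suffixes:
            end = L + self.umi_len + self.tail
            if len(seq) < end:
                continue
            if not seq.startswith(suffix):
                continue
            umi = seq[L:L + self.umi_len]
            if not _UMI_BASES.issuperset(umi):
                continue
            if seq[L + self.umi_len:end] != self.spacer + self.anchor:
                continue
            return L, umi, end
        return None


def compile_r1_grammar(oligo: OligoConfig, dialect: str) -> MotifMatcher:
    """Read-1 grammar: any adapter suffix down to the dialect minimum."""
    if dialect not in DIALECTS:
        raise OligoConfigError(f"unknown dialect {dialect!r}")
    spacer = oligo.spacer if dialect == "spacer" else ""
    if dialect == "spacer" and not spacer:
        raise OligoConfigError("spacer dialect requires a non-empty spacer")
    lo = oligo.min_suffix_for(dialect)
    lengths = range(lo, len(oligo.adapter) + 1)
    return MotifMatcher(oligo.adapter, oligo.umi_len, spacer, oligo.anchor, lengths)


def compile_r2_grammar(oligo: OligoConfig, dialect: str) -> MotifMatcher:
    """Read-2 rescue grammar: only the configured short adapter remnants."""
    if dialect not in DIALECTS:
        raise OligoConfigError(f"unknown dialect {dialect!r}")
    spacer = oligo.spacer if dialect == "spacer" else ""
    lengths = [len(s) for s in oligo.r2_adapter_suffixes]
    return MotifMatcher(oligo.adapter, oligo.umi_len, spacer, oligo.anchor, lengths)


def extract_umis(pairs: Iterable[ReadPair], oligo: OligoConfig,
                 dialect: str = "spacer"
                 ) -> tuple[list[UmiExtraction], list[ReadPair], dict[str, int]]:
    """Partition pairs into UMI extractions and non-UMI pairs.

    The read-1 grammar is tried on mate 1 first; only if it fails is the
    read-2 grammar tried on mate 2 (read 1 is the designed configuration,
    read 2 the tagmentation rescue). On a read-2 match the mates are swapped
    so the trimmed UMI-bearing sequence is always mate 1 of the output.
    """
    g1 = compile_r1_grammar(oligo, dialect)
    g2 = compile_r2_grammar(oligo, dialect)
    extractions: list[UmiExtraction] = []
    non_umi: list[ReadPair] = []
    counters = {"n_r1_umi": 0, "n_r2_umi": 0, "n_non_umi": 0}
    for p in pairs:
        hit = g1.match(p.seq1)
        if hit is not None:
            L, umi, motif_len = hit
            trimmed = ReadPair(p.read_id, p.seq1[motif_len:], p.seq2,
                               p.qual1[motif_len:], p.qual2)
            extractions.append(UmiExtraction(p.read_id, umi, "R1", L, trimmed))
            counters["n_r1_umi"] += 1
            continue
        hit = g2.match(p.seq2)
        if hit is not None:
            L, umi, motif_len = hit
            trimmed = ReadPair(p.read_id, p.seq2[motif_len:], p.seq1,
                               p.qual2[motif_len:], p.qual1)
            extractions.append(UmiExtraction(p.read_id, umi, "R2", L, trimmed))
            counters["n_r2_umi"] += 1
            continue
        non_umi.append(p)
        counters["n_non_umi"] += 1
    return extractions, non_umi, counters


def crop_and_filter(items: Iterable[ReadPair | UmiExtraction],
                    max_len: int = 75, min_len: int = 25
                    ) -> Iterator[ReadPair | UmiExtraction]:
    """Crop both mates to max_len and keep only pairs with both mates
    strictly longer than min_len."""
    for item in items:
        pair = item.pair if isinstance(item, UmiExtraction) else item
        cropped = ReadPair(pair.read_id, pair.seq1[:max_len], pair.seq2[:max_len],
                           pair.qual1[:max_len], pair.qual2[:max_len])
        if len(cropped.seq1) <= min_len or len(cropped.seq2) <= min_len:
            continue
        if isinstance(item, UmiExtraction):
            yield UmiExtraction(item.read_id, item.umi, item.source,
                                item.matched_adapter_suffix_len, cropped)
        else:
            yield cropped


__all__ = [
    "DEFAULT_ADAPTER", "DEFAULT_SPACER", "DIALECTS", "MotifMatcher",
    "OligoConfig", "OligoConfigError", "UmiExtraction", "compile_r1_grammar",
    "compile_r2_grammar", "crop_and_filter", "extract_umis",
]
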
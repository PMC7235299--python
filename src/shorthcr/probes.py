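"""Split-initiator probe design against a target transcript.

A probe set tiles the target with adjacent 25-nt windows and attaches
half of the 21-nt HCR initiator to each probe, so a functional
initiator is reconstituted only where both probes bind side by side —
a single mis-bound probe cannot trigger amplification:

  p_long  (39 nt) = initiator[10..21] + 2-nt spacer + revcomp(upstream window)
  p_short (36 nt) = revcomp(downstream window) + 2-nt spacer + initiator[1..9]

(1-based initiator positions: 1-9 is the 9-nt stem-complement half,
10-21 the toehold-complement plus first-3-nt-of-stem half).  The 39-nt
probe takes the upstream (5') window so the two initiator halves
juxtapose at the window junction under antiparallel hybridization.

Binding sites are filtered to 45-55% GC; off-target screening is an
exact complementary k-mer scan (default k=15) over a background
transcriptome, standing in for a homology search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import DesignConfig
from .hairpins import HairpinPair
from .seqcore import gc_fraction, longest_homopolymer, normalize, reverse_complement

__all__ = [
    "TargetTranscript",
    "ProbeWindowPair",
    "SplitProbePair",
    "ProbeSet",
    "OffTargetHit",
    "tile_candidate_windows",
    "make_split_probe_pair",
    "design_probe_set",
    "offtarget_screen",
    "write_order_sheet",
    "InsufficientCandidatesError",
]


class InsufficientCandidatesError(RuntimeError):
    """Fewer compliant window pairs than requested probe pairs."""


@dataclass(frozen=True)
class TargetTranscript:
    """A sense-strand transcript sequence (mRNA given as DNA)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProbeWindowPair:
    """Two adjacent binding windows on the target, 0-based half-open."""

    upstream: tuple[int, int]
    downstream: tuple[int, int]
    gap: int = 0

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.upstream[0], self.downstream[1])


@dataclass(frozen=True)
class SplitProbePair:
    """The 39-nt and 36-nt oligos for one window pair."""

    p_long: str
    p_short: str
    windows: ProbeWindowPair
    initiator_id: str = ""


@dataclass(frozen=True)
class ProbeSet:
    """All probe pairs designed for one target."""

    target_id: str
    items: tuple[tuple[ProbeWindowPair, SplitProbePair], ...]
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.items)

    @property
    def probes(self) -> list[SplitProbePair]:
        return [p for _, p in self.items]


def tile_candidate_windows(
    target: TargetTranscript, config: DesignConfig | None = None
) -> list[ProbeWindowPair]:
    """Scan every start position for a compliant adjacent window pair.

    Both windows must fall in the binding GC band (inclusive) and
    respect the homopolymer cap.  Ordered by position; an empty result
    is not an error.
    """
    config = config or DesignConfig()
    w, gap = config.window_len, config.gap
    footprint = 2 * w + gap
    if len(target) < footprint:
        raise ValueError(
            f"target {target.id!r} is {len(target)} nt; needs >= {footprint}"
        )
    out: list[ProbeWindowPair] = []
    for i in range(len(target) - footprint + 1):
        up = target.seq[i : i + w]
        down = target.seq[i + w + gap : i + footprint]
        if all(
            config.binding_gc_min <= gc_fraction(s) <= config.binding_gc_max
            and longest_homopolymer(s) <= config.homopolymer_max
            for s in (up, down)
        ):
            out.append(ProbeWindowPair((i, i + w), (i + w + gap, i + footprint), gap))
    return out


def make_split_probe_pair(
    windows: ProbeWindowPair,
    target: TargetTranscript,
    initiator: str,
    spacer: str = "AA",
    initiator_id: str = "",
) -> SplitProbePair:
    """Assemble the 39-nt and 36-nt probes for one window pair.

    Requires the default 21-nt initiator (9-nt toehold + 12-nt stem
    geometry); the split point is fixed 3 nt into the stem complement,
    partitioning the initiator 9 | 12 with no overlap and no gap.
    """
    initiator = normalize(initiator)
    if len(initiator) != 21:
        raise ValueError(
            f"split probes require a 21-nt initiator (got {len(initiator)} nt); "
            "use the default 9/12/9 hairpin geometry"
        )
    spacer = normalize(spacer)
    if len(spacer) != 2:
        raise ValueError("spacer must be exactly 2 nt")
    (u0, u1), (d0, d1) = windows.upstream, windows.downstream
    if not (0 <= u0 < u1 <= d0 < d1 <= len(target)):
        raise ValueError("windows out of bounds or overlapping")
    up_bind = reverse_complement(target.seq[u0:u1])
    down_bind = reverse_complement(target.seq[d0:d1])
    p_long = initiator[9:21] + spacer + up_bind
    p_short = down_bind + spacer + initiator[0:9]
    return SplitProbePair(p_long, p_short, windows, initiator_id)


def _greedy_select(
    candidates: list[ProbeWindowPair], n: int, min_spacing: int
) -> list[ProbeWindowPair]:
    """Leftmost greedy pick with start-to-start distance >= min_spacing."""
    chosen: list[ProbeWindowPair] = []
    last_end = -1
    last_start = None
    for c in candidates:
        s, e = c.footprint
        if s >= last_end and (last_start is None or s - last_start >= min_spacing):
            chosen.append(c)
            last_end, last_start = e, s
            if len(chosen) == n:
                break
    return chosen


def design_probe_set(
    target: TargetTranscript,
    hairpin: HairpinPair,
    n_pairs: int | None = None,
    config: DesignConfig | None = None,
    seed: int | None = None,
) -> ProbeSet:
    """Select up to ``n_pairs`` non-overlapping window pairs and build probes.

    Selection is a maximal-spacing heuristic: the largest uniform
    start-to-start spacing that still yields ``n_pairs`` compliant,
    non-overlapping pairs is found by bisection, spreading probes along
    the transcript.  Ties resolve leftmost.  Deterministic; ``seed`` is
    recorded in the set for provenance only.
    """
    config = config or DesignConfig()
    n = n_pairs if n_pairs is not None else config.n_pairs
    if n < 1:
        raise ValueError("n_pairs must be >= 1")
    candidates = tile_candidate_windows(target, config)
    dense = _greedy_select(candidates, n, 0)
    if len(dense) < n:
        msg = (
            f"only {len(dense)} compliant non-overlapping window pairs on "
            f"{target.id!r} (requested {n})"
        )
        if not (config.allow_partial and dense):
            raise InsufficientCandidatesError(msg)
        warnings.warn(msg + "; emitting a partial set", stacklevel=2)
        chosen = dense
    else:
        lo, hi = 0, len(target)  # invariant: spacing lo always succeeds
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if len(_greedy_select(candidates, n, mid)) >= n:
                lo = mid
            else:
                hi = mid - 1
        chosen = _greedy_select(candidates, n, lo)
    items = tuple(
        (
            w,
            make_split_probe_pair(
                w, target, hairpin.initiator, config.spacer, hairpin.set_id
            ),
        )
        for w in chosen
    )
    return ProbeSet(target.id, items, config.model_dump(), seed)


@dataclass(frozen=True)
class OffTargetHit:
    probe_index: int
    role: str  # probe_long | probe_short
    background_id: str
    kmer: str


def offtarget_screen(
    probes: ProbeSet,
    background: list[TargetTranscript],
    k: int | None = None,
) -> list[OffTargetHit]:
    """Flag probes whose binding region is complementary to a background transcript.

    A probe is flagged when any k-mer of its binding region has its
    reverse complement in a background transcript other than the probe
    set's own target.  Exact k-mer matching (default k = 15), not
    alignment.
    """
    k = k if k is not None else int(probes.config.get("offtarget_k", 15))
    if k < 8:
        raise ValueError("k must be >= 8")
    others = [t for t in background if t.id != probes.target_id]
    if not others:
        warnings.warn("background contains no transcripts other than the target", stacklevel=2)
        return []
    index: dict[str, set[str]] = {}
    for t in others:
        kmers = index.setdefault(t.id, set())
        for i in range(len(t.seq) - k + 1):
            kmers.add(t.seq[i : i + k])
    hits: list[OffTargetHit] = []
    for idx, (windows, pair) in enumerate(probes.items):
        wlen = windows.upstream[1] - windows.upstream[0]
        regions = {
            "probe_long": pair.p_long[-wlen:],
            "probe_short": pair.p_short[:wlen],
        }
        for role, region in regions.items():
            query = reverse_complement(region)  # == the target window sequence
            for bg_id, kmers in index.items():
                for i in range(len(query) - k + 1):
                    km = query[i : i + k]
                    if km in kmers:
                        hits.append(OffTargetHit(idx, role, bg_id, km))
                        break
    return hits


def write_order_sheet(probe_set: ProbeSet, path: str | Path) -> pd.DataFrame:
    """Write the order-sheet TSV (and a matching FASTA next to it).

    Columns: oligo_name, sequence_5to3, length_nt, role, window_start,
    window_end, initiator_id.  Returns the DataFrame written.
    """
    if not probe_set.items:
        raise ValueError("probe set is empty")
    path = Path(path)
    rows = []
    records = []
    for idx, (windows, pair) in enumerate(probe_set.items, start=1):
        for role, seq, (w0, w1) in (
            ("probe_long", pair.p_long, windows.upstream),
            ("probe_short", pair.p_short, windows.downstream),
        ):
            name = f"{probe_set.target_id}_pair{idx:02d}_{role}"
            rows.append(
                {
                    "oligo_name": name,
                    "sequence_5to3": seq,
                    "length_nt": len(seq),
                    "role": role,
                    "window_start": w0,
                    "window_end": w1,
                    "initiator_id": pair.initiator_id,
                }
            )
            records.append(
                SeqRecord(Seq(seq), id=name, description=f"{role} window={w0}-{w1}")
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    SeqIO.write(records, path.with_suffix(".fasta"), "fasta")
    return df
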
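"""FASTA I/O, synthetic transcript generation, and oligo export.

FASTA handling goes through Biopython; sequences are normalized on read
(uppercase, U->T) so RNA targets can be supplied directly.  The
synthetic transcript generator produces seeded i.i.d. sequences at a
chosen GC fraction and stands in for real mRNAs in tests and examples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hairpins import HairpinPair
from .probes import TargetTranscript
from .seqcore import normalize

__all__ = [
    "read_fasta",
    "write_fasta",
    "SyntheticTranscript",
    "synth_transcript",
    "write_hairpin_order_sheet",
]


def read_fasta(path: str | Path) -> list[TargetTranscript]:
    """Read a multi-record FASTA into normalized transcripts.

    An empty file returns an empty list with a warning; a file whose
    first non-blank character is not '>' raises with the line number.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected a FASTA header line")
            break
    else:
        warnings.warn(f"{path}: empty FASTA, no records", stacklevel=2)
        return []
    records = list(SeqIO.parse(path, "fasta"))
    return [TargetTranscript(r.id, normalize(str(r.seq))) for r in records]


def write_fasta(records: list[TargetTranscript], path: str | Path) -> None:
    """Write transcripts as 60-column wrapped FASTA."""
    SeqIO.write(
        [SeqRecord(Seq(t.seq), id=t.id, description="") for t in records],
        Path(path),
        "fasta",
    )


@dataclass(frozen=True)
class SyntheticTranscript:
    """A seeded random transcript with a controlled GC fraction."""

    id: str
    length: int
    gc: float
    seed: int
    seq: str

    def as_target(self) -> TargetTranscript:
        return TargetTranscript(self.id, self.seq)


def synth_transcript(
    length: int, gc: float = 0.5, seed: int = 0, id: str | None = None
) -> SyntheticTranscript:
    """Draw an i.i.d. transcript: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2.

    Deterministic for a fixed seed.  For length >= 500 the realized GC
    fraction concentrates within ~0.03 of the requested value.
    """
    if length < 50:
        raise ValueError("length must be >= 50 (one probe-pair footprint)")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(bases[rng.choice(4, size=length, p=p)])
    name = id if id is not None else f"synthetic_L{length}_gc{gc:g}_s{seed}"
    return SyntheticTranscript(name, length, gc, seed, seq)


def write_hairpin_order_sheet(pair: HairpinPair, path: str | Path) -> pd.DataFrame:
    """Export one amplifier set as an order-sheet TSV plus annotated FASTA.

    TSV columns: oligo_name, sequence_5to3, length_nt, five_prime_mod
    (amino linker on the hairpins for fluorophore coupling).  The FASTA
    headers annotate the domain decomposition.
    """
    path = Path(path)
    spec = pair.spec
    linker = pair.reagents.linker if pair.reagents else "ssH"
    rows = [
        {"oligo_name": f"{pair.set_id}_H1", "sequence_5to3": pair.h1,
         "length_nt": len(pair.h1), "five_prime_mod": f"{linker}-amino"},
        {"oligo_name": f"{pair.set_id}_H2", "sequence_5to3": pair.h2,
         "length_nt": len(pair.h2), "five_prime_mod": f"{linker}-amino"},
        {"oligo_name": f"{pair.set_id}_initiator", "sequence_5to3": pair.initiator,
         "length_nt": len(pair.initiator), "five_prime_mod": ""},
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    geom = f"toehold={len(spec.toehold)} stem={len(spec.stem)} loop={len(spec.loop)}"
    records = [
        SeqRecord(Seq(pair.h1), id=f"{pair.set_id}_H1",
                  description=f"a+b+c+b' {geom} shift={spec.shift}"),
        SeqRecord(Seq(pair.h2), id=f"{pair.set_id}_H2",
                  description=f"b'+a'+b+c' {geom}"),
        SeqRecord(Seq(pair.initiator), id=f"{pair.set_id}_initiator",
                  description="(a+b)'"),
    ]
    SeqIO.write(records, path.with_suffix(".fasta"), "fasta")
    return df
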
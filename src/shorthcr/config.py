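"""Design configuration.

One pydantic model carries every tunable the designers read, with the
published design rules as defaults: 9/12/9 hairpin geometry (42 nt),
toehold GC < 40%, stem GC > 60%, stem G/C imbalance >= 4, probe binding
sites of 25 nt at 45-55% GC.  Serializes round-trip stably to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

__all__ = ["DesignConfig"]


class DesignConfig(BaseModel):
    """All designer tunables with the standard short-hairpin defaults."""

    # hairpin geometry (nt); 9/12/9 gives the 42-nt hairpin
    toehold_len: int = Field(9, ge=6, le=10)
    stem_len: int = Field(12, ge=8, le=16)
    loop_len: int = Field(9, ge=6, le=10)
    shift: int = Field(0, ge=0, le=2, description="transition-site shift, nt")
    keep_unpaired_transition: bool = Field(
        False,
        description="leave the shifted transition bases unpaired instead of "
        "extending the stem duplex",
    )

    # composition rules (strict inequalities on GC fractions)
    toehold_gc_max: float = Field(0.40, gt=0.0, le=1.0)
    stem_gc_min: float = Field(0.60, ge=0.0, lt=1.0)
    stem_imbalance_min: int = Field(4, ge=0)
    imbalance_mandatory: bool = True
    homopolymer_max: int = Field(4, ge=2)

    # probe design
    window_len: int = Field(25, ge=15)
    binding_gc_min: float = Field(0.45, ge=0.0, le=1.0)
    binding_gc_max: float = Field(0.55, ge=0.0, le=1.0)
    spacer: str = Field("AA", pattern=r"^[ACGT]{2}$")
    gap: int = Field(0, ge=0, le=2, description="nt between paired target windows")
    n_pairs: int = Field(5, ge=1)
    allow_partial: bool = False
    offtarget_k: int = Field(15, ge=8)

    # structure / orthogonality checks
    fold_margin: float = Field(2.0, gt=0.0, description="kcal/mol")
    crosstalk_run_threshold: int = Field(6, ge=4)

    # search
    max_iterations: int = Field(100_000, ge=1)
    seed: int | None = None

    @model_validator(mode="after")
    def _bands_ordered(self) -> "DesignConfig":
        if self.binding_gc_min > self.binding_gc_max:
            raise ValueError("binding GC band is inverted")
        if self.loop_len - 2 * self.shift < 3:
            raise ValueError("transition shift leaves a loop shorter than 3 nt")
        return self

    @property
    def hairpin_len(self) -> int:
        """Total hairpin length: toehold + 2*stem + loop (shift-invariant)."""
        return self.toehold_len + 2 * self.stem_len + self.loop_len

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DesignConfig":
        try:
            is_file = Path(source).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        return cls.model_validate(json.loads(text))
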
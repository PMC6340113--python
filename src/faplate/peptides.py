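"""Registry of TAMRA-labelled RyR2 CaM-binding-domain (CaMBD) peptides.

Human RyR2 numbering (UniProtKB Q92736).  The registry covers the four
proposed CaMBD regions (1a, 1b, 2, 3), the elongated CaMBD2(+) used for
hydrophobic-anchor studies together with its W3587A and F3603A variants,
the Ser-2031-phosphorylated CaMBD1b, and a ``null_probe`` entry standing
for free 5-TAMRA dye (no peptide, no binding) used as the assay's
no-binding control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Peptide", "load_registry", "get_peptide", "TAMRA_EPSILON_556"]

#: 5-TAMRA molar extinction coefficient at 556 nm (M^-1 cm^-1).
TAMRA_EPSILON_556 = 103_000.0


@dataclass(frozen=True)
class Peptide:
    id: str
    ryr2_span: tuple[int, int] | None
    sequence: str
    modifications: tuple[dict, ...] = field(default_factory=tuple)
    label: str = "5-TAMRA"

    def __post_init__(self) -> None:
        if self.ryr2_span is not None:
            start, end = self.ryr2_span
            if end < start:
                raise ValueError(f"{self.id}: invalid residue span")
            for mod in self.modifications:
                pos = mod.get("position")
                if pos is not None and not (start <= pos <= end):
                    raise ValueError(
                        f"{self.id}: modification at {pos} outside span "
                        f"{start}-{end}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, ryr2_position: int) -> str:
        """One-letter residue at an absolute RyR2 sequence position."""
        if self.ryr2_span is None:
            raise ValueError(f"{self.id} has no RyR2 span")
        start, end = self.ryr2_span
        if not start <= ryr2_position <= end:
            raise IndexError(f"position {ryr2_position} outside {start}-{end}")
        return self.sequence[ryr2_position - start]

    @property
    def binds(self) -> bool:
        """False only for the free-dye control probe."""
        return self.id != "null_probe"


def load_registry() -> dict[str, Peptide]:
    raw = json.loads(
        resources.files("faplate.data").joinpath("peptides.json").read_text()
    )
    reg: dict[str, Peptide] = {}
    for pid, rec in raw.items():
        span = tuple(rec["ryr2_span"]) if rec["ryr2_span"] else None
        reg[pid] = Peptide(
            id=pid,
            ryr2_span=span,
            sequence=rec["sequence"],
            modifications=tuple(rec["modifications"]),
            label=rec["label"],
        )
    return reg


_REGISTRY: dict[str, Peptide] | None = None


def get_peptide(peptide_id: str) -> Peptide:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry()
    try:
        return _REGISTRY[peptide_id]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown peptide {peptide_id!r}; known: {known}") from None
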
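"""Nearest-neighbor free-energy model for RNA:RNA duplexes at 37 degC.

The model scores purely intermolecular duplexes: a duplex initiation
penalty, stacked-pair free energies for helical (adjacent) base pairs,
length-dependent penalties for bulges and internal loops that interrupt
the helix, and a destabilizing correction for A:U / G:U pairs closing
either duplex end.

Watson-Crick stack values follow the published 37 degC RNA/RNA
nearest-neighbor set (Xia/Turner); stacks involving G:U wobbles carry
approximate published values. Loop penalties are a simplified monotone
schedule: they increase with loop size and no stacking energy is awarded
across an interrupted step. All constants are shipped here and versioned
via ``MODEL_VERSION`` so reported energies are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MODEL_VERSION = "smoltmir-nn-1.0"

#: base pairs allowed in a helix (G:U wobble included; seed matching is
#: stricter and handled by the caller)
WATSON_CRICK = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}
ALL_PAIRS = WATSON_CRICK | WOBBLE

# Canonical stack entries keyed "XY/WZ": top strand 5'-XY-3', bottom
# strand 3'-WZ-5' (read left to right, so X pairs W and Y pairs Z).
_CANONICAL_STACKS = {
    # Watson-Crick / Watson-Crick (Xia et al. 37 degC, kcal/mol)
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
    # stacks involving one or two G:U wobbles (approximate published values)
    "AG/UU": -0.55,
    "AU/UG": -1.36,
    "CG/GU": -1.41,
    "CU/GG": -2.11,
    "GG/CU": -1.53,
    "GU/CG": -2.51,
    "UG/AU": -1.00,
    "UU/AG": -0.76,
    "GG/UU": -0.50,
    "GU/UG": 0.47,
    "UG/GU": -0.44,
}

_DEFAULT_WOBBLE_STACK = -0.50  # mild stabilization for uncatalogued wobble stacks


def _mirror(key: str) -> str:
    # stack read from the other strand: 5'-XY-3'/3'-WZ-5'  ==  5'-ZW-3'/3'-YX-5'
    top, bottom = key.split("/")
    return bottom[::-1] + "/" + top[::-1]


def _build_stack_table() -> dict[str, float]:
    table: dict[str, float] = {}
    for key, dg in _CANONICAL_STACKS.items():
        table.setdefault(key, dg)
        table.setdefault(_mirror(key), dg)
    # complete the 36-entry table for every adjacent pair combination
    for x, w in ALL_PAIRS:
        for y, z in ALL_PAIRS:
            table.setdefault(f"{x}{y}/{w}{z}", _DEFAULT_WOBBLE_STACK)
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Shipped duplex free-energy constants (kcal/mol, 37 degC)."""

    stacks: dict[str, float] = field(default_factory=_build_stack_table)
    init: float = 4.09
    terminal_au: float = 0.45
    #: bulge penalty by bulge length 1..9 (monotone non-decreasing)
    bulge: tuple[float, ...] = tuple(3.8 + 0.5 * n for n in range(9))
    #: internal-loop penalty by total unpaired length 2..18 (monotone)
    internal: tuple[float, ...] = tuple(1.7 + 0.3 * n for n in range(17))
    version: str = MODEL_VERSION

    def pairable(self, a: str, b: str) -> bool:
        return (a, b) in ALL_PAIRS

    def stack_energy(self, top5: str, top3: str, bot5: str, bot3: str) -> float:
        """Energy of the stack 5'-top5 top3-3' over 3'-bot5 bot3-5'."""
        return self.stacks[f"{top5}{top3}/{bot5}{bot3}"]

    def bulge_penalty(self, n: int) -> float:
        if not 1 <= n <= len(self.bulge):
            raise ValueError(f"bulge length {n} outside 1..{len(self.bulge)}")
        return self.bulge[n - 1]

    def internal_penalty(self, n1: int, n2: int) -> float:
        total = n1 + n2
        if not 2 <= total <= len(self.internal) + 1:
            raise ValueError(f"internal loop size {total} out of range")
        return self.internal[total - 2]

    def terminal_penalty(self, a: str, b: str) -> float:
        """Closing-pair correction: A:U and G:U duplex ends pay +0.45."""
        return self.terminal_au if (a, b) in (WATSON_CRICK - {("C", "G"), ("G", "C")}) | WOBBLE else 0.0


DEFAULT_MODEL = EnergyModel()
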
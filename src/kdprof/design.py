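"""Titration design: the channel concentration grid an experiment follows.

An affinity-enrichment titration presents an immobilized ligand to a lysate
at a series of nominal concentrations, one TMT channel per concentration.
The default design is a zero control followed by ten three-fold dilution
steps down from 100 uM (i.e. 100/3**k for k = 9..0), measured in three
biological replicates, for four probes in four lysate conditions
(cytosolic/nuclear fraction x EDTA/Mg buffer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Tuple

DEFAULT_PROBES: Tuple[str, ...] = (
    "b_InsP6",
    "b_5PCP_InsP5",
    "b_1PCP_InsP5",
    "b_15PCP2_InsP4",
)
FRACTIONS: Tuple[str, ...] = ("cytosolic", "nuclear")
METALS: Tuple[str, ...] = ("EDTA", "Mg")
DEFAULT_CONDITIONS: Tuple[Tuple[str, str], ...] = tuple(product(FRACTIONS, METALS))


@dataclass(frozen=True)
class TitrationDesign:
    """Channel concentrations (uM), replicate count, probes and conditions.

    Invariants: the first concentration is 0 (the no-ligand control) and the
    remaining concentrations are strictly increasing and positive.
    """

    channel_concentrations: Tuple[float, ...]
    n_replicates: int = 3
    probes: Tuple[str, ...] = DEFAULT_PROBES
    conditions: Tuple[Tuple[str, str], ...] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.channel_concentrations)
        object.__setattr__(self, "channel_concentrations", conc)
        if len(conc) < 2:
            raise ValueError("design needs at least a control and one dose")
        if conc[0] != 0.0:
            raise ValueError("first channel must be the 0 uM control")
        if any(c <= 0 for c in conc[1:]):
            raise ValueError("non-control concentrations must be positive")
        if any(b <= a for a, b in zip(conc[1:], conc[2:])):
            raise ValueError("concentrations must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        object.__setattr__(self, "probes", tuple(self.probes))
        object.__setattr__(
            self, "conditions", tuple((f, m) for f, m in self.conditions)
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_concentrations)

    @property
    def top_concentration(self) -> float:
        return self.channel_concentrations[-1]

    @property
    def lowest_nonzero(self) -> float:
        return self.channel_concentrations[1]

    def condition_label(self, fraction: str, metal: str) -> str:
        return f"{fraction}-{metal}"


def default_design(n_replicates: int = 3) -> TitrationDesign:
    """The 11-plex design: 0 uM plus a three-fold series from 100 uM down.

    Exact values 100/3**k (k = 9..0) are used; display rounding is left to
    the caller. Three biological replicates by default.
    """
    conc = (0.0,) + tuple(100.0 / 3.0**k for k in range(9, -1, -1))
    return TitrationDesign(channel_concentrations=conc, n_replicates=n_replicates)
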
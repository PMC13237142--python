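"""Pyrophosphoprotein candidate funnel: motifs, disorder, mass arithmetic.

Pyrophosphorylation sites sit on pre-phosphorylated serines/threonines that
are typically primed by acidophilic or proline-directed Ser/Thr kinases and
lie inside intrinsically disordered regions. The funnel therefore scans
each protein sequence for configurable kinase motifs (an anchored S/T
acceptor plus positional residue-class constraints), profiles disorder with
a windowed residue-propensity smoother (TOP-IDP scale, min-max scaled to
[0, 1]; externally computed per-residue scores can be supplied instead),
and calls a protein a candidate when at least one acceptor falls inside a
disordered interval. The built-in motifs are documented approximations of
the acidophilic / proline-directed classes, user-overridable; no fidelity
to any proprietary scoring matrix is claimed.

Pyrophosphopeptides betray themselves in CID spectra by a neutral loss of
pyrophosphate (H4P2O7, 177.9432 Da); the mass utilities here compute
monoisotopic masses from standard atomic masses and decide whether an
observed precursor/fragment m/z difference matches that loss at a given
charge and ppm tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic atomic masses (Da), CODATA/IUPAC standard values.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Pyrophosphate neutral loss observed for pyrophosphopeptides.
PYROPHOSPHATE_FORMULA: Mapping[str, int] = {"H": 4, "P": 2, "O": 7}

#: TOP-IDP per-residue disorder propensity (order-promoting negative,
#: disorder-promoting positive); min-max scaled to [0, 1] before windowing.
TOP_IDP: Mapping[str, float] = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}


@dataclass(frozen=True)
class MotifDef:
    """Kinase-motif pattern anchored on a phospho-acceptor.

    ``branches`` is an OR-list of constraint maps; each maps a position
    offset (relative to the acceptor at 0) to the set of allowed residues
    there. A position matches when the acceptor residue is in ``acceptor``
    and all constraints of at least one branch hold; constraints that fall
    outside the sequence do not match. The wildcard residue X never
    satisfies a constrained position.
    """

    name: str
    motif_class: str  # "acidophilic" or "proline_directed"
    branches: Tuple[Mapping[int, frozenset], ...]
    acceptor: frozenset = frozenset("ST")

    def __post_init__(self) -> None:
        if not self.acceptor <= frozenset("ST"):
            raise ValueError("acceptor must be restricted to S/T")
        for branch in self.branches:
            for off, residues in branch.items():
                if off == 0:
                    raise ValueError("offset 0 is the acceptor itself")
                bad = set(residues) - AMINO_ACIDS
                if bad:
                    raise ValueError(f"motif {self.name!r}: illegal residue codes {sorted(bad)}")


def _branch(d: Dict[int, str]) -> Mapping[int, frozenset]:
    return {off: frozenset(res) for off, res in d.items()}


#: Default motif set: proline-directed = S/T-P; acidophilic = CK2-like
#: (acidic at +2 or +3) or CK1-like (acidic at -3).
DEFAULT_MOTIFS: Tuple[MotifDef, ...] = (
    MotifDef("proline_directed", "proline_directed", (_branch({1: "P"}),)),
    MotifDef(
        "acidophilic",
        "acidophilic",
        (_branch({2: "DE"}), _branch({3: "DE"}), _branch({-3: "DE"})),
    ),
)


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based acceptor coordinate
    motif: str
    residue: str


@dataclass
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] and thresholded intervals.

    Intervals are 1-based closed [start, end] maximal runs of windowed
    score >= threshold, non-overlapping and sorted.
    """

    scores: np.ndarray
    window: int
    threshold: float
    intervals: List[Tuple[int, int]]

    def in_disorder(self, position: int) -> bool:
        if not 1 <= position <= len(self.scores):
            raise ValueError(f"position {position} outside sequence of length {len(self.scores)}")
        return any(a <= position <= b for a, b in self.intervals)


@dataclass
class PyroCandidate:
    protein_id: str
    hits: List[Tuple[int, str, bool]]  # (position, motif name, in_disorder)
    candidate: bool


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS and aa != "X":
            raise ValueError(f"illegal character {aa!r} at position {i + 1}")


def scan_motifs(
    sequence: str, motifs: Sequence[MotifDef] = DEFAULT_MOTIFS
) -> List[MotifHit]:
    """All acceptor positions where a motif's constraints hold.

    Overlapping hits and multiple motifs at the same acceptor are all
    reported, with 1-based coordinates.
    """
    _check_sequence(sequence)
    hits: List[MotifHit] = []
    L = len(sequence)
    for motif in motifs:
        for i, aa in enumerate(sequence):
            if aa not in motif.acceptor:
                continue
            for branch in motif.branches:
                ok = True
                for off, allowed in branch.items():
                    j = i + off
                    if not 0 <= j < L or sequence[j] not in allowed:
                        ok = False
                        break
                if ok:
                    hits.append(MotifHit(position=i + 1, motif=motif.name, residue=aa))
                    break
    hits.sort(key=lambda h: (h.position, h.motif))
    return hits


def disorder_profile(
    sequence: str,
    window: int = 21,
    threshold: float = 0.5,
    scale: Mapping[str, float] = TOP_IDP,
    external_scores: Optional[Sequence[float]] = None,
) -> DisorderProfile:
    """Windowed-propensity disorder profile with thresholded intervals.

    The per-residue propensity (min-max scaled over the supplied table) is
    averaged in a sliding window of ``window`` residues, shrinking
    symmetrically at the termini. When ``external_scores`` is given (e.g.
    per-residue scores from a dedicated disorder predictor), those scores
    are used directly and only the thresholding is applied.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if external_scores is not None:
        scores = np.asarray(external_scores, dtype=float)
        if len(scores) != len(sequence):
            raise ValueError("external scores must match sequence length")
    else:
        lo, hi = min(scale.values()), max(scale.values())
        span = hi - lo
        try:
            raw = np.array([(scale[aa] - lo) / span for aa in sequence])
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} missing from the propensity table") from None
        half = window // 2
        n = len(raw)
        scores = np.empty(n)
        cumsum = np.concatenate([[0.0], np.cumsum(raw)])
        for i in range(n):
            # symmetric shrink: the window narrows equally on both sides
            k = min(half, i, n - 1 - i)
            scores[i] = (cumsum[i + k + 1] - cumsum[i - k]) / (2 * k + 1)
    above = scores >= threshold
    intervals: List[Tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start + 1, i))
            start = None
    if start is not None:
        intervals.append((start + 1, len(above)))
    return DisorderProfile(scores=scores, window=window, threshold=threshold, intervals=intervals)


def candidate_filter(
    protein_id: str, hits: Sequence[MotifHit], profile: DisorderProfile
) -> PyroCandidate:
    """Candidate verdict: >= 1 acceptor inside a disordered interval."""
    annotated = [(h.position, h.motif, profile.in_disorder(h.position)) for h in hits]
    return PyroCandidate(
        protein_id=protein_id,
        hits=annotated,
        candidate=any(in_dis for _, _, in_dis in annotated),
    )


def run_screen(
    records: Sequence[Tuple[str, str]],
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    window: int = 21,
    threshold: float = 0.5,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Run the full funnel over FASTA-style (id, sequence) records.

    Returns a per-protein candidate table and the funnel summary
    (proteins in, proteins with motif hits, candidates out).
    """
    rows = []
    n_with_hits = 0
    for pid, seq in records:
        hits = scan_motifs(seq, motifs)
        profile = disorder_profile(seq, window=window, threshold=threshold)
        cand = candidate_filter(pid, hits, profile)
        if hits:
            n_with_hits += 1
        rows.append(
            {
                "protein_id": pid,
                "n_motif_hits": len(hits),
                "n_hits_in_disorder": sum(1 for _, _, d in cand.hits if d),
                "candidate": cand.candidate,
                "hit_positions": ";".join(str(p) for p, _, _ in cand.hits),
                "hit_motifs": ";".join(m for _, m, _ in cand.hits),
            }
        )
    table = pd.DataFrame(rows, columns=[
        "protein_id", "n_motif_hits", "n_hits_in_disorder", "candidate",
        "hit_positions", "hit_motifs"])
    summary = {
        "n_input": len(records),
        "n_with_motif": n_with_hits,
        "n_candidates": int(table["candidate"].sum()) if len(table) else 0,
    }
    return table, summary


# ---------------------------------------------------------------------------
# mass arithmetic

def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an element->count map over C,H,N,O,P,S."""
    total = 0.0
    for element, count in formula.items():
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r}")
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        total += MONOISOTOPIC_MASS[element] * count
    return total


def neutral_loss_match(
    precursor_mz: float,
    fragment_mz: float,
    charge: int,
    tolerance_ppm: float = 20.0,
    loss_formula: Mapping[str, int] = PYROPHOSPHATE_FORMULA,
) -> bool:
    """Does the precursor/fragment m/z gap match the pyrophosphate loss?

    True when |(precursor_mz - fragment_mz) * charge - mass(loss)| is
    within ``tolerance_ppm`` of the loss mass.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if precursor_mz <= 0 or fragment_mz <= 0:
        raise ValueError("m/z values must be positive")
    loss = monoisotopic_mass(loss_formula)
    observed = (precursor_mz - fragment_mz) * charge
    return abs(observed - loss) <= loss * tolerance_ppm * 1e-6
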
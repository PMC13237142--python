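"""Synthetic titration data, sequences and gene sets with known ground truth.

Every downstream stage of the pipeline is exercised against data generated
here, so all generators write a truth sidecar and are fully deterministic
under a seed. The quantification generator emulates the statistical
structure of reporter-ion titration data: binder proteins follow Hill-like
enrichment curves, non-binders are flat, per-channel noise is multiplicative
lognormal, and dropout is intensity-dependent (missing-not-at-random,
concentrated in the lowest intensity decile). Base abundances span more
than four orders of magnitude and double as an iBAQ proxy.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import TitrationDesign, default_design
from .io import ROW_INDEX, QuantTable

__all__ = [
    "TitrationDesign",
    "default_design",
    "NoiseModel",
    "generate_quant_tables",
    "generate_sequences",
    "generate_cohort",
    "generate_gene_sets",
    "hill_response",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Residue pools used to compose ordered and disordered sequence blocks.
# Both exclude S and T so that phospho-acceptor sites occur only where the
# generator plants them (keeps the candidate-funnel truth exact).
ORDER_POOL = "ILVFWMA"
DISORDER_POOL = "PEKQGDR"


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise plus intensity-dependent dropout.

    cv: coefficient of variation of the lognormal factor (mean 1).
    missing_rate_low: dropout probability for values in the lowest global
    intensity decile (values above the decile are never dropped).
    """

    cv: float = 0.12
    missing_rate_low: float = 0.10

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0.0 <= self.missing_rate_low <= 1.0:
            raise ValueError("missing_rate_low must lie in [0, 1]")

    @property
    def sigma(self) -> float:
        """Lognormal shape parameter giving the configured CV."""
        return float(np.sqrt(np.log1p(self.cv**2)))


def hill_response(c: np.ndarray, baseline: float, plateau: float, kd: float, slope: float) -> np.ndarray:
    """Hill-like binding curve R(c) = b + (t-b) c^h / (c^h + K^h); R(0) = b."""
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, float(baseline))
    nz = c > 0
    ch = c[nz] ** slope
    out[nz] = baseline + (plateau - baseline) * ch / (ch + kd**slope)
    return out


def generate_quant_tables(
    design: Optional[TitrationDesign] = None,
    n_proteins: int = 1000,
    binder_fraction: float = 0.25,
    kd_range: Tuple[float, float] = (0.1, 30.0),
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[QuantTable, pd.DataFrame]:
    """Simulate reporter abundances for every probe x condition x replicate.

    For each (protein, probe, condition) the protein is a binder with
    probability ``binder_fraction``; binders get a dissociation constant K
    drawn log-uniformly from ``kd_range`` (uM), a Hill slope in [0.8, 1.5],
    a baseline response in [0.02, 0.15] of the plateau (1.0), and their
    expected channel abundance follows the Hill curve scaled by the
    protein's base abundance. Non-binders are flat at the base abundance.

    Returns the QuantTable and a ground-truth table with one row per
    (protein, probe, condition).
    """
    design = design or default_design()
    noise = noise or NoiseModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0.0 <= binder_fraction <= 1.0:
        raise ValueError("binder_fraction must lie in [0, 1]")
    lo, hi = float(kd_range[0]), float(kd_range[1])
    if not (0 < lo < hi):
        raise ValueError("kd_range must be positive with low < high")

    conc = np.asarray(design.channel_concentrations)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    # base abundance: log10-normal, sd 1.1 decades -> >= 4 decades span
    base = 10.0 ** rng.normal(6.0, 1.1, size=n_proteins)
    ibaq = pd.Series(base, index=pd.Index(ids, name="protein_id"), name="iBAQ")

    truth_rows = []
    expected: Dict[Tuple[str, str, str], np.ndarray] = {}
    for probe in design.probes:
        for fraction, metal in design.conditions:
            is_binder = rng.random(n_proteins) < binder_fraction
            kd = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_proteins)
            slope = rng.uniform(0.8, 1.5, size=n_proteins)
            b = rng.uniform(0.02, 0.15, size=n_proteins)
            t = np.ones(n_proteins)
            resp = np.empty((n_proteins, len(conc)))
            for i in range(n_proteins):
                if is_binder[i]:
                    resp[i] = hill_response(conc, b[i], t[i], kd[i], slope[i])
                else:
                    resp[i] = 1.0
            expected[(probe, fraction, metal)] = resp * base[:, None]
            for i in range(n_proteins):
                truth_rows.append(
                    {
                        "protein_id": ids[i],
                        "probe": probe,
                        "fraction": fraction,
                        "metal": metal,
                        "is_binder": bool(is_binder[i]),
                        "true_kd": kd[i] if is_binder[i] else np.nan,
                        "true_hill_slope": slope[i] if is_binder[i] else np.nan,
                        "baseline": b[i] if is_binder[i] else 1.0,
                        "plateau": t[i] if is_binder[i] else 1.0,
                        "base_abundance": base[i],
                    }
                )
    truth = pd.DataFrame(truth_rows)

    frames = []
    index_rows = []
    for (probe, fraction, metal), exp in expected.items():
        for rep in range(1, design.n_replicates + 1):
            if noise.cv > 0:
                factor = rng.lognormal(-0.5 * noise.sigma**2, noise.sigma, size=exp.shape)
            else:
                factor = 1.0
            frames.append(exp * factor)
            index_rows.extend(
                (pid, probe, fraction, metal, rep) for pid in ids
            )
    values = np.vstack(frames)
    if noise.missing_rate_low > 0:
        decile = np.quantile(values, 0.1)
        at_risk = values <= decile
        drop = at_risk & (rng.random(values.shape) < noise.missing_rate_low)
        values = np.where(drop, np.nan, values)
    data = pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(index_rows, names=ROW_INDEX),
        columns=range(design.n_channels),
    )
    return QuantTable(design, data, ibaq), truth


# ---------------------------------------------------------------------------
# sequences for the pyrophospho candidate funnel

#: Planted-motif instances. Each maps a motif name to the literal residue
#: string planted and the 0-based offset of the phospho-acceptor within it.
MOTIF_INSTANCES: Mapping[str, Tuple[str, int]] = {
    "proline_directed": ("SP", 0),
    "acidophilic": ("SAE", 0),  # acceptor with acidic residue at +2
}


def _random_block(pool: str, length: int, rng: np.random.Generator) -> List[str]:
    return list(rng.choice(list(pool), size=length))


def generate_sequences(
    n: int,
    planted_motifs: Sequence[Tuple[str, bool]] = (),
    disorder_block: Tuple[int, int] = (120, 220),
    length: int = 340,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Generate protein sequences with a designed central disordered block.

    ``planted_motifs`` lists (motif_name, in_disorder) plants applied to
    every sequence; motif names must be keys of MOTIF_INSTANCES. Positions
    are chosen away from block edges so the windowed disorder score is
    unambiguous. Returns (records, truth sidecar) where truth has one row
    per planted site: protein_id, motif, position (1-based acceptor
    coordinate), in_disorder.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    d0, d1 = disorder_block
    if not (0 < d0 < d1 <= length):
        raise ValueError("disorder_block must lie within the sequence")
    for name, _ in planted_motifs:
        if name not in MOTIF_INSTANCES:
            raise ValueError(f"unknown motif {name!r}; known: {sorted(MOTIF_INSTANCES)}")
        if any(aa not in AMINO_ACIDS for aa in MOTIF_INSTANCES[name][0]):
            raise ValueError(f"motif {name!r} contains illegal residue codes")

    records: List[Tuple[str, str]] = []
    truth_rows = []
    margin = 15
    for i in range(n):
        seq = (
            _random_block(ORDER_POOL, d0, rng)
            + _random_block(DISORDER_POOL, d1 - d0, rng)
            + _random_block(ORDER_POOL, length - d1, rng)
        )
        pid = f"SEQ{i:05d}"
        for name, in_disorder in planted_motifs:
            inst, acc_off = MOTIF_INSTANCES[name]
            if in_disorder:
                start = int(rng.integers(d0 + margin, d1 - margin - len(inst)))
            else:
                start = int(rng.integers(margin, d0 - margin - len(inst)))
            seq[start : start + len(inst)] = list(inst)
            truth_rows.append(
                {
                    "protein_id": pid,
                    "motif": name,
                    "position": start + acc_off + 1,
                    "in_disorder": bool(in_disorder),
                }
            )
        records.append((pid, "".join(seq)))
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "motif", "position", "in_disorder"])
    return records, truth


def generate_cohort(
    n: int,
    in_disorder_rate: float = 0.35,
    out_disorder_rate: float = 0.35,
    motif: str = "proline_directed",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Cohort where a known fraction of proteins carries an in-disorder site.

    ``in_disorder_rate`` of the proteins get an acceptor motif inside the
    disordered block (true funnel candidates), ``out_disorder_rate`` get the
    motif in an ordered region, and the remainder carry no acceptor at all.
    The per-protein truth column ``is_candidate`` marks the planted rate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if in_disorder_rate + out_disorder_rate > 1.0:
        raise ValueError("rates must sum to <= 1")
    records: List[Tuple[str, str]] = []
    rows = []
    u = rng.random(n)
    for i in range(n):
        if u[i] < in_disorder_rate:
            plants = [(motif, True)]
            candidate = True
        elif u[i] < in_disorder_rate + out_disorder_rate:
            plants = [(motif, False)]
            candidate = False
        else:
            plants = []
            candidate = False
        recs, _ = generate_sequences(1, plants, rng=rng)
        records.append((f"SEQ{i:05d}", recs[0][1]))
        rows.append({"protein_id": f"SEQ{i:05d}", "is_candidate": candidate})
    truth = pd.DataFrame(rows)
    return records, truth


# ---------------------------------------------------------------------------
# gene sets

def generate_gene_sets(
    universe: Sequence[str],
    set_sizes: Sequence[int],
    enrichment_spec: Optional[Tuple[str, Sequence[str], int]] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Dict[str, Tuple[str, List[str]]]:
    """Random gene sets plus one engineered to overlap a query exactly.

    ``enrichment_spec`` is (set_name, query_ids, forced_overlap): the named
    set shares exactly ``forced_overlap`` members with the query and draws
    the rest from outside it. Sets are returned GMT-style:
    name -> (description, members).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    universe = list(dict.fromkeys(universe))
    for size in set_sizes:
        if size > len(universe):
            raise ValueError(f"set size {size} exceeds universe size {len(universe)}")
    sets: Dict[str, Tuple[str, List[str]]] = {}
    for j, size in enumerate(set_sizes):
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets[f"random_set_{j:03d}"] = ("randomly drawn set", list(members))
    if enrichment_spec is not None:
        name, query, k = enrichment_spec
        query = [q for q in dict.fromkeys(query) if q in universe]
        size = set_sizes[-1] if set_sizes else k
        if k > size:
            raise ValueError(f"forced overlap {k} exceeds set size {size}")
        if k > len(query):
            raise ValueError(f"forced overlap {k} exceeds query size {len(query)}")
        outside = [u for u in universe if u not in set(query)]
        if size - k > len(outside):
            raise ValueError("not enough non-query ids for the requested set size")
        members = list(rng.choice(query, size=k, replace=False)) + list(
            rng.choice(outside, size=size - k, replace=False)
        )
        sets[name] = ("engineered overlap set", sorted(members))
    return sets
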
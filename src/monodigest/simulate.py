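"""Synthetic proteomes and identification tables for end-to-end testing.

The generator emulates the statistical structure the analysis assumes:

* a proteome with human-like residue composition and log-normal protein
  lengths (stand-in for a curated protein database);
* protein abundances log-normal on the log10 scale, calibrated so the
  realised max/min ratio spans a target dynamic range (~6 orders of
  magnitude, the within-cell range of protein copy numbers);
* replicate-to-replicate multiplicative noise at a target CV, applied per
  (protein, condition, replicate) and shared by that protein's peptides —
  mimicking sample-handling variation that moves a protein's whole peptide
  complement together;
* abundance-dependent stochastic peptide detection through a logistic
  curve in log10 abundance, a deliberately simple stand-in for the
  intensity-biased precursor sampling of data-dependent acquisition (DDA);
* q-values drawn from a two-component mixture placing a configurable
  fraction of rows above the confidence threshold.

Everything is driven by explicit integer seeds: identical models and seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .digestion import CleavageRule, DigestConfig, digest
from .fasta_io import Proteome, ProteinRecord

__all__ = [
    "HUMAN_RESIDUE_FREQUENCIES",
    "ProteomeModel",
    "AbundanceModel",
    "ObservationModel",
    "generate_proteome",
    "assign_abundances",
    "simulate_identifications",
    "write_manifest",
]

#: Average amino-acid composition of the human proteome (fractions, sum 1).
HUMAN_RESIDUE_FREQUENCIES: Dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "E": 0.071, "Q": 0.048, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}
_TOTAL = sum(HUMAN_RESIDUE_FREQUENCIES.values())
HUMAN_RESIDUE_FREQUENCIES = {k: v / _TOTAL for k, v in HUMAN_RESIDUE_FREQUENCIES.items()}


@dataclass
class ProteomeModel:
    """Synthetic proteome: i.i.d. residues, log-normal lengths.

    ``length_median`` (residues) and ``length_sigma`` (log-scale s.d.)
    parameterise the length distribution; defaults approximate the human
    proteome (median ~375 residues, right-skewed tail).
    """

    n_proteins: int = 1000
    length_median: float = 375.0
    length_sigma: float = 0.8
    residue_frequencies: Dict[str, float] = field(
        default_factory=lambda: dict(HUMAN_RESIDUE_FREQUENCIES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        total = sum(self.residue_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies must sum to 1 (got {total!r})")


@dataclass
class AbundanceModel:
    """Log10-normal protein abundances spanning a target dynamic range.

    The log10 scale parameter is calibrated from the sample size so the
    *expected realised* log10(max/min) equals ``dynamic_range_orders``
    (using the Blom approximation for normal extreme-order statistics).
    ``location_log10`` centres the distribution in arbitrary intensity
    units (default 1e6).
    """

    dynamic_range_orders: float = 6.0
    location_log10: float = 6.0
    seed: int = 0


@dataclass
class ObservationModel:
    """Replicated, noisy, stochastically-sampled observation of a digest.

    ``replicate_cv`` is the coefficient of variation of the multiplicative
    log-normal replicate noise (shared by all peptides of a protein within
    one replicate; ``peptide_cv`` adds optional independent peptide-level
    noise on top).  ``detection_midpoint_log10``/``detection_slope``
    define the logistic detection probability in log10 parent abundance;
    slope 0 with midpoint -inf gives detection = 1 everywhere (the default
    uses a finite midpoint).  ``missed_share_factor`` down-weights the
    abundance share of peptides carrying missed cleavages.
    ``q_above_fraction`` of rows draw q-values above 0.01 (uniform on
    (0.01, 1]); the rest draw uniform on [0, 0.01).
    """

    n_replicates: int = 3
    replicate_cv: float = 0.15
    peptide_cv: float = 0.0
    detection_midpoint_log10: Optional[float] = None  # None -> always detected
    detection_slope: float = 1.5
    missed_share_factor: float = 0.3
    q_above_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.replicate_cv < 0 or self.peptide_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not 0.0 <= self.q_above_fraction <= 1.0:
            raise ValueError("q_above_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def detection_probability(self, log10_abundance) -> np.ndarray:
        """Logistic P(detect | log10 abundance); 1 everywhere if no midpoint."""
        x = np.asarray(log10_abundance, dtype=float)
        if self.detection_midpoint_log10 is None:
            return np.ones_like(x)
        from scipy.special import expit

        return expit(self.detection_slope * (x - self.detection_midpoint_log10))


def generate_proteome(model: ProteomeModel) -> Proteome:
    """Draw a synthetic proteome; deterministic for a fixed seed.

    Accessions are SYN000001, SYN000002, ... in order.
    """
    rng = np.random.default_rng(model.seed)
    letters = sorted(model.residue_frequencies)
    probs = np.array([model.residue_frequencies[a] for a in letters])
    lengths = np.exp(
        np.log(model.length_median) + model.length_sigma * rng.standard_normal(model.n_proteins)
    )
    lengths = np.maximum(1, np.round(lengths)).astype(int)
    letter_arr = np.array(list(letters))
    records = []
    for i, L in enumerate(lengths, start=1):
        seq = "".join(letter_arr[rng.choice(len(letters), size=L, p=probs)])
        records.append(
            ProteinRecord(accession=f"SYN{i:06d}", description=f"SYN{i:06d} synthetic protein", sequence=seq)
        )
    return Proteome(records=records, source_path="<synthetic>")


def _calibrated_sigma(orders: float, n: int) -> float:
    """Log10 s.d. such that E[log10 max - log10 min] ~ ``orders`` for n draws."""
    if n < 2:
        return orders / 2.0
    # Blom approximation to the expected largest standard-normal order statistic
    e_max = stats.norm.ppf((n - 0.375) / (n + 0.25))
    return orders / (2.0 * e_max)


def assign_abundances(proteome: Proteome, model: AbundanceModel) -> Dict[str, float]:
    """Draw one positive abundance per protein, log10-normal, seeded."""
    rng = np.random.default_rng(model.seed)
    n = proteome.n_records
    sigma = _calibrated_sigma(model.dynamic_range_orders, n)
    log10_a = model.location_log10 + sigma * rng.standard_normal(n)
    return {rec.accession: float(10.0 ** x) for rec, x in zip(proteome, log10_a)}


def simulate_identifications(
    proteome: Proteome,
    abundances: Mapping[str, float],
    rule: CleavageRule,
    config: DigestConfig = DigestConfig(),
    obs: ObservationModel = ObservationModel(),
    conditions: Sequence[str] = ("cond1",),
) -> pd.DataFrame:
    """Simulate a long-format identification table from a digest.

    Each protein is digested under ``rule``/``config``; its abundance is
    shared equally among its zero-missed peptides, with missed-cleavage
    products receiving that share scaled by ``missed_share_factor**missed``.
    Every (peptide, condition, replicate) is detected independently with
    probability ``obs.detection_probability(log10 parent abundance)``;
    detected rows carry the noisy abundance and a simulated q-value.

    Returns a DataFrame with the canonical identification-table columns.
    Raises if the digest yields no peptides; an empty table (all-zero
    detection) is returned with a logged warning.
    """
    import logging

    rng = np.random.default_rng(obs.seed)
    rep_sigma = float(np.sqrt(np.log1p(obs.replicate_cv**2)))
    pep_sigma = float(np.sqrt(np.log1p(obs.peptide_cv**2)))

    rows: List[dict] = []
    any_peptides = False
    for rec in proteome:
        peptides = digest(rec, rule, config)
        if not peptides:
            continue
        any_peptides = True
        parent = float(abundances[rec.accession])
        n_zero = sum(1 for p in peptides if p.missed == 0)
        base_share = parent / max(n_zero, 1)
        p_detect = float(obs.detection_probability(np.log10(parent)))
        # distinct sequences: table rows are keyed (protein, peptide)
        shares: Dict[str, float] = {}
        for p in peptides:
            share = base_share * (obs.missed_share_factor ** p.missed)
            shares[p.sequence] = shares.get(p.sequence, 0.0) + share
        seqs = sorted(shares)
        for condition in conditions:
            for replicate in range(1, obs.n_replicates + 1):
                rep_noise = (
                    float(np.exp(rep_sigma * rng.standard_normal()))
                    if obs.replicate_cv > 0
                    else 1.0
                )
                detected = rng.random(len(seqs)) < p_detect
                for seq, hit in zip(seqs, detected):
                    if not hit:
                        continue
                    abundance = shares[seq] * rep_noise
                    if obs.peptide_cv > 0:
                        abundance *= float(np.exp(pep_sigma * rng.standard_normal()))
                    if rng.random() < obs.q_above_fraction:
                        q = 0.01 + 0.99 * rng.random()
                    else:
                        q = 0.01 * rng.random()
                    rows.append(
                        {
                            "protein": rec.accession,
                            "peptide": seq,
                            "condition": condition,
                            "replicate": replicate,
                            "abundance": abundance,
                            "q_value": q,
                        }
                    )
    if not any_peptides:
        raise ValueError("digest produced no peptides under this configuration")
    if not rows:
        logging.getLogger(__name__).warning(
            "simulate_identifications: no peptides detected (detection probability ~ 0)"
        )
    return pd.DataFrame(
        rows, columns=["protein", "peptide", "condition", "replicate", "abundance", "q_value"]
    )


def write_manifest(path, **models) -> None:
    """Dump model parameters (dataclasses or plain values) as JSON."""
    payload = {}
    for key, value in models.items():
        try:
            payload[key] = asdict(value)
        except TypeError:
            payload[key] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
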
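"""Proteome-wide digestion summaries and complexity relative to a reference protease.

The central question these metrics answer: how much does switching from a
multi-residue protease (trypsin, cutting after K and R) to a monosubstrate
protease (LysC after K, ArgC after R) reduce the number of peptide analytes,
and what fraction of the proteome still yields at least one peptide passing
the missed-cleavage/length criteria?

Peptides are counted two ways, because both readings of "number of peptides"
are defensible: as positional occurrences (every (protein, start, end) event)
and as distinct peptide sequences proteome-wide.  All ratios are reported
against a named reference rule, trypsin by default.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .digestion import (
    STANDARD_AA,
    CleavageRule,
    DigestConfig,
    PRESETS,
    compile_rule,
    digest,
)
from .fasta_io import Proteome

__all__ = [
    "DigestSummary",
    "RelativeComplexity",
    "digest_proteome",
    "coverage_pct",
    "relative_complexity",
    "residue_scan",
]


@dataclass
class DigestSummary:
    """Per-protein and proteome-wide passing-peptide counts for one rule."""

    rule_name: str
    per_protein: Dict[str, int]
    total_peptides: int
    distinct_sequences: int
    n_proteins_covered: int
    n_proteins_total: int


@dataclass
class RelativeComplexity:
    """Complexity of one rule normalised to a reference rule."""

    rule_name: str
    reference_name: str
    peptide_ratio: float
    median_per_protein_ratio: float
    coverage_pct: float


def digest_proteome(
    proteome: Proteome, rule: CleavageRule, config: DigestConfig = DigestConfig()
) -> DigestSummary:
    """Digest every record and aggregate counts.

    Occurrence counts are per protein; distinct sequences are pooled
    proteome-wide (the same sequence arising in two proteins, or at two
    positions, counts once).  Deterministic for fixed inputs.
    """
    if proteome.n_records == 0:
        raise ValueError("cannot digest an empty proteome")
    per_protein: Dict[str, int] = {}
    distinct = set()
    total = 0
    for rec in proteome:
        peps = digest(rec, rule, config)
        per_protein[rec.accession] = len(peps)
        total += len(peps)
        distinct.update(p.sequence for p in peps)
    return DigestSummary(
        rule_name=rule.name,
        per_protein=per_protein,
        total_peptides=total,
        distinct_sequences=len(distinct),
        n_proteins_covered=sum(1 for v in per_protein.values() if v > 0),
        n_proteins_total=proteome.n_records,
    )


def coverage_pct(summary: DigestSummary) -> float:
    """Percentage of database proteins yielding >= 1 passing peptide."""
    if summary.n_proteins_total <= 0:
        raise ValueError("summary covers no proteins")
    return 100.0 * summary.n_proteins_covered / summary.n_proteins_total


def relative_complexity(summary: DigestSummary, reference: DigestSummary) -> RelativeComplexity:
    """Normalise ``summary`` to ``reference`` (same proteome universe).

    Medians of peptides-per-protein are taken over all database proteins,
    zero-peptide proteins included.  The reference median of a realistic
    digest is positive; if it is zero the ratio is NaN.
    """
    if set(summary.per_protein) != set(reference.per_protein):
        raise ValueError("summaries cover different protein universes")
    if reference.total_peptides == 0:
        raise ValueError("reference digest produced no peptides")
    med = statistics.median(summary.per_protein.values())
    ref_med = statistics.median(reference.per_protein.values())
    return RelativeComplexity(
        rule_name=summary.rule_name,
        reference_name=reference.rule_name,
        peptide_ratio=summary.total_peptides / reference.total_peptides,
        median_per_protein_ratio=(med / ref_med) if ref_med > 0 else float("nan"),
        coverage_pct=coverage_pct(summary),
    )


def summaries_to_frame(
    summaries: Iterable[DigestSummary], reference: DigestSummary
) -> pd.DataFrame:
    """Tabulate summaries with ratios vs ``reference``, sorted by peptide_ratio."""
    rows = []
    for s in summaries:
        rel = relative_complexity(s, reference)
        rows.append(
            {
                "rule": s.rule_name,
                "total_peptides": s.total_peptides,
                "distinct_sequences": s.distinct_sequences,
                "proteins_covered": s.n_proteins_covered,
                "proteins_total": s.n_proteins_total,
                "coverage_pct": rel.coverage_pct,
                "peptide_ratio": rel.peptide_ratio,
                "median_per_protein_ratio": rel.median_per_protein_ratio,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["peptide_ratio", "rule"], kind="mergesort")
        .reset_index(drop=True)
    )


def residue_scan(
    proteome: Proteome,
    config: DigestConfig = DigestConfig(),
    reference: Optional[CleavageRule] = None,
    include_presets: bool = True,
) -> pd.DataFrame:
    """Scan all single-residue rules (20 standard residues x {C, N} termini).

    Returns one row per rule — the 40 single-residue rules, the presets,
    and the reference — sorted by peptide_ratio.  The reference (default
    trypsin) appears with ratio exactly 1.
    """
    reference = compile_rule(reference) if reference is not None else PRESETS["trypsin"]
    rules: List[CleavageRule] = [reference]
    seen = {(reference.residues, reference.terminus)}
    if include_presets:
        for preset in PRESETS.values():
            key = (preset.residues, preset.terminus)
            if key not in seen:
                seen.add(key)
                rules.append(preset)
    for aa in STANDARD_AA:
        for term in ("C", "N"):
            rule = CleavageRule(name=f"{aa}@{term}", residues=frozenset(aa), terminus=term)
            if (rule.residues, rule.terminus) not in seen:
                seen.add((rule.residues, rule.terminus))
                rules.append(rule)
    ref_summary = digest_proteome(proteome, reference, config)
    summaries = [ref_summary] + [digest_proteome(proteome, r, config) for r in rules[1:]]
    return summaries_to_frame(summaries, ref_summary)
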
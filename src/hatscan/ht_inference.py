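"""Horizontal-transfer inference from TE vs. host-gene divergence.

A transposable element inherited vertically accumulates divergence
between host species at least as fast as neutral nuclear sequence, so a
TE that is markedly *less* diverged between two species than their
nuclear genes points to a horizontal transfer (HT) after the species
split.  For each species pair the classifier compares the TE p-distance
against the expectation set by a nuclear gene (e.g. Adh or Amd) with a
one-sample chi-square goodness-of-fit test on the TE alignment's
(different, identical) site counts, df = 1.

Decision rule: vertical transmission (VT) whenever the TE divergence is
greater than or equal to the gene divergence, regardless of p; HT
requires both a smaller TE divergence and a significant chi-square.
When an expected cell count falls below the floor the chi-square
approximation is untrustworthy and the verdict is ``inconclusive``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2 as _chi2

from .divergence import PairwiseAlignment, p_distance

__all__ = ["MarkerPair", "HTVerdict", "DegenerateExpectationError",
           "ht_chi2_test", "ht_screen", "verdicts_to_table"]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_EXPECTED = 5.0


class DegenerateExpectationError(ValueError):
    """Gene divergence of exactly 0 or 1 gives a degenerate expectation."""


@dataclass(frozen=True)
class MarkerPair:
    """One species pair with its TE alignment and a nuclear-gene alignment."""

    species_a: str
    species_b: str
    te_aln: PairwiseAlignment
    gene_aln: PairwiseAlignment
    gene_name: str = "gene"


@dataclass(frozen=True)
class HTVerdict:
    species_a: str
    species_b: str
    gene_name: str
    d_te: float
    d_gene: float
    chi2: float
    p_value: float
    call: str  # "HT" | "VT" | "inconclusive"


def ht_chi2_test(mp: MarkerPair, alpha: float = DEFAULT_ALPHA,
                 min_expected: float = DEFAULT_MIN_EXPECTED) -> HTVerdict:
    """Chi-square goodness-of-fit of TE divergence against the gene expectation.

    With ``L`` compared TE sites, observed counts are
    ``O = (diffs, L - diffs)`` and expected counts
    ``E = (d_gene * L, (1 - d_gene) * L)``; the statistic is
    ``sum((O - E)^2 / E)`` on one degree of freedom, two-sided, with
    directionality enforced by the decision rule.
    """
    d_te = p_distance(mp.te_aln)
    d_gene = p_distance(mp.gene_aln)
    if d_gene <= 0.0 or d_gene >= 1.0:
        raise DegenerateExpectationError(
            f"{mp.species_a}/{mp.species_b}: gene divergence {d_gene} "
            "gives an expected count of zero"
        )
    L = mp.te_aln.compared_sites
    o_diff = mp.te_aln.diffs
    e_diff = d_gene * L
    e_same = (1.0 - d_gene) * L
    stat = (o_diff - e_diff) ** 2 / e_diff + ((L - o_diff) - e_same) ** 2 / e_same
    p = float(_chi2.sf(stat, df=1))
    if min(e_diff, e_same) < min_expected:
        call = "inconclusive"
    elif d_te < d_gene and p < alpha:
        call = "HT"
    else:
        call = "VT"
    return HTVerdict(mp.species_a, mp.species_b, mp.gene_name,
                     d_te, d_gene, stat, p, call)


def ht_screen(groups: list[MarkerPair], alpha: float = DEFAULT_ALPHA,
              correction: str = "none",
              min_expected: float = DEFAULT_MIN_EXPECTED) -> list[HTVerdict]:
    """One verdict per marker pair, optionally Bonferroni-adjusted.

    Per-pair errors (degenerate expectation, empty alignments) do not
    abort the screen: the affected pair is reported as inconclusive with
    NaN statistics.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    if not groups:
        raise ValueError("ht_screen needs at least one marker pair")
    eff_alpha = alpha / len(groups) if correction == "bonferroni" else alpha
    out: list[HTVerdict] = []
    for mp in groups:
        try:
            out.append(ht_chi2_test(mp, eff_alpha, min_expected))
        except (DegenerateExpectationError, ValueError):
            out.append(HTVerdict(mp.species_a, mp.species_b, mp.gene_name,
                                 float("nan"), float("nan"), float("nan"),
                                 float("nan"), "inconclusive"))
    out.sort(key=lambda v: (v.species_a, v.species_b, v.gene_name))
    return out


def verdicts_to_table(verdicts: list[HTVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_a": v.species_a,
                "species_b": v.species_b,
                "gene": v.gene_name,
                "d_te": v.d_te,
                "d_gene": v.d_gene,
                "chi2": v.chi2,
                "p_value": v.p_value,
                "call": v.call,
            }
            for v in verdicts
        ]
    )
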
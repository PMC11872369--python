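"""Phylogenetic grouping of survival rates: section means and section-vs-rest
tests per garden.

Species are grouped by phylogenetic section (a named clade within the
genus); for each garden, each section's survival rates are compared against
all other species at that garden with a Mann-Whitney U test. For small
samples (combined n <= 20) the test is exact by full enumeration of rank
assignments, handling ties by counting over the actual value multiset; the
two-sided p doubles the smaller one-sided tail, capped at 1. Larger samples
use the normal approximation with tie correction. No multiple-comparison
correction is applied (sections x gardens are reported as-is, flagged in
the output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EXACT_ENUMERATION_MAX_N = 20


@dataclass
class SectionComparison:
    section: str
    garden: str
    section_mean: float
    rest_mean: float
    U: float
    p_value: float | None
    n_section: int
    n_rest: int
    method: str = "exact"
    note: str = "no multiple-comparison correction applied"


def _u_statistic(group: np.ndarray, rest: np.ndarray) -> float:
    """Mann-Whitney U of ``group`` (ties count one half)."""
    wins = (group[:, None] > rest[None, :]).sum()
    ties = (group[:, None] == rest[None, :]).sum()
    return float(wins + 0.5 * ties)


def exact_mannwhitney(group, rest) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration.

    Enumerates all C(n, m) assignments of the pooled values to the group,
    computes the exact null distribution of U (ties handled by the value
    multiset itself), and doubles the smaller one-sided tail (capped at 1).
    Returns (U_observed, p).
    """
    group = np.asarray(group, float)
    rest = np.asarray(rest, float)
    m, n = len(group), len(rest)
    if m + n > EXACT_ENUMERATION_MAX_N:
        raise ValueError(f"exact enumeration limited to combined n <= "
                         f"{EXACT_ENUMERATION_MAX_N}")
    pooled = np.concatenate([group, rest])
    u_obs = _u_statistic(group, rest)
    total = comb(m + n, m)
    idx = np.arange(m + n)
    n_le = n_ge = 0
    for chosen in combinations(idx, m):
        g = pooled[list(chosen)]
        r = np.delete(pooled, list(chosen))
        u = _u_statistic(g, r)
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def section_means(sr_long: pd.DataFrame,
                  assignment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean SR per section x garden (missing species excluded pairwise).

    ``sr_long`` needs columns species, garden, SR and either a section
    column or a separate ``assignment`` table (species, section). Species
    without an assignment are flagged and excluded.
    """
    df = sr_long.copy()
    if "section" not in df.columns:
        if assignment is None:
            raise ValueError("need a section column or an assignment table")
        df = df.merge(assignment[["species", "section"]], on="species",
                      how="left")
    unassigned = df[df["section"].isna()]["species"].unique()
    if len(unassigned):
        log.warning("species without section assignment excluded: %s",
                    sorted(unassigned))
        df = df.dropna(subset=["section"])
    df = df.dropna(subset=["SR"])
    return (df.groupby(["section", "garden"], sort=True)["SR"]
            .agg(mean_sr="mean", n="size").reset_index())


def section_vs_rest_test(sr_long: pd.DataFrame, garden: str, section: str,
                         assignment: pd.DataFrame | None = None
                         ) -> SectionComparison:
    """Mann-Whitney comparison of one section's SRs against all other
    species' SRs at one garden (exact for combined n <= 20)."""
    df = sr_long.copy()
    if "section" not in df.columns:
        if assignment is None:
            raise ValueError("need a section column or an assignment table")
        df = df.merge(assignment[["species", "section"]], on="species",
                      how="left")
    at = df[(df["garden"] == garden) & df["SR"].notna()]
    grp = at[at["section"] == section]["SR"].to_numpy(float)
    rest = at[at["section"] != section]["SR"].to_numpy(float)
    if len(grp) < 2 or len(rest) < 2:
        log.warning("group too small for %s at %s (n=%d vs %d); no p-value",
                    section, garden, len(grp), len(rest))
        return SectionComparison(section, garden,
                                 float(grp.mean()) if len(grp) else np.nan,
                                 float(rest.mean()) if len(rest) else np.nan,
                                 np.nan, None, len(grp), len(rest),
                                 method="none")
    if len(grp) + len(rest) <= EXACT_ENUMERATION_MAX_N:
        u, p = exact_mannwhitney(grp, rest)
        method = "exact"
    else:
        res = stats.mannwhitneyu(grp, rest, alternative="two-sided",
                                 method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "normal-approx"
    return SectionComparison(section, garden, float(grp.mean()),
                             float(rest.mean()), u, p,
                             len(grp), len(rest), method=method)


def all_section_tests(sr_long: pd.DataFrame,
                      assignment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Section-vs-rest tests for every section x garden combination."""
    df = sr_long if "section" in sr_long.columns else sr_long.merge(
        assignment[["species", "section"]], on="species", how="left")
    rows = []
    for garden in sorted(df["garden"].dropna().unique()):
        for section in sorted(df["section"].dropna().unique()):
            cmp_ = section_vs_rest_test(df, garden, section)
            rows.append(cmp_.__dict__)
    return pd.DataFrame(rows)


def garden_rank_pattern(sr_long: pd.DataFrame,
                        assignment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-section ordering of gardens by mean SR (ascending).

    Returns one row per section with the ordered garden list, the means,
    and a flag for degenerate cases (section present in < 2 gardens or
    tied means).
    """
    means = section_means(sr_long, assignment)
    rows = []
    for section, grp in means.groupby("section"):
        grp = grp.sort_values(["mean_sr", "garden"], kind="stable")
        order = grp["garden"].tolist()
        tied = grp["mean_sr"].duplicated().any()
        rows.append({
            "section": section,
            "order": order,
            "means": dict(zip(grp["garden"], grp["mean_sr"].round(6))),
            "degenerate": len(order) < 2,
            "ties": bool(tied),
        })
    return pd.DataFrame(rows)
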
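"""Survival rates, standardisation against natives, and HS-SR alignment.

From a per-individual garden inventory this module computes the
species-specific survival rate SR = 1 - MR over a study period, where the
mortality rate MR counts only deaths attributed to climate or unknown
causes (deaths from other causes stay in the denominator — those
individuals existed — but not the numerator). Each ex-situ species' SR is
then standardised against the SRs of locally native reference species,
SSR = (SR - SR_mu) / sigma, with sigma the sample (n-1) standard deviation
over the native set.

Survival is classified with the same three-level scale as habitat
suitability: below a minimal SR of 0.1 a site is unsuitable for the
species regardless of the native baseline; within 2 native standard
deviations of the native mean (SSR >= -2) it is optimal (surviving better
than natives is not penalised); in between — surviving but not thriving —
it is marginal. Comparing the HS class with the SR class ordinally yields
the alignment verdict: agree, over (HS above SR) or under (HS below SR).

A worked-example fixture of published per-species survival rates across
three UK botanic gardens (with phylogenetic section assignments) ships
with the package; see :func:`load_survival_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .transfer import CLASS_ORDER, HS_CLASSES

DEFAULT_CAUSES_KEPT = frozenset({"climate", "unknown"})

#: Garden code -> local district used for HS aggregation.
GARDEN_DISTRICTS = {"KEW": "Richmond", "RBGE": "Lothian", "WESB": "Cotswold"}


@dataclass
class SurvivalThresholds:
    """Thresholds tying SR/SSR and HS to the three-level suitability scale."""

    minimal_sr: float = 0.1     # below this, unsuitable outright
    ssr_window: float = 2.0     # the +/-2 native-sd band
    hs_t_low: float = 0.3
    hs_t_high: float = 0.6

    def __post_init__(self):
        if not 0 < self.minimal_sr < 1:
            raise ValueError("minimal_sr must be in (0, 1)")
        if self.ssr_window <= 0:
            raise ValueError("ssr_window must be > 0")
        if not 0 <= self.hs_t_low < self.hs_t_high <= 1:
            raise ValueError("need 0 <= hs_t_low < hs_t_high <= 1")


@dataclass
class SSRResult:
    species: str
    region: str
    sr: float
    native_mean: float
    native_sd: float
    ssr: float
    sr_class: str | None = None


@dataclass
class AlignmentVerdict:
    species: str
    region: str
    hs_class: str
    sr_class: str
    verdict: str


def compute_sr(inventory: pd.DataFrame,
               causes_kept=DEFAULT_CAUSES_KEPT,
               period: tuple[int, int] | None = None) -> pd.DataFrame:
    """Survival table: one row per species x garden.

    MR = (deaths with cause in ``causes_kept``, within ``period`` if given)
    / initial individuals; SR = 1 - MR. Rows with zero initial individuals
    are flagged (``valid = False``) for downstream exclusion.
    """
    inv = inventory
    if period is not None:
        inv = inv[(inv["year"] >= period[0]) & (inv["year"] <= period[1])]
    rows = []
    for (species, garden), grp in inv.groupby(["species", "garden"], sort=True):
        n_initial = len(grp)
        dead = grp[grp["status"] == "dead"]
        n_retained = int(dead["death_cause"].isin(causes_kept).sum())
        if n_initial == 0:
            rows.append({"species": species, "garden": garden,
                         "n_initial": 0, "n_deaths_retained": 0,
                         "MR": np.nan, "SR": np.nan, "valid": False})
            continue
        mr = n_retained / n_initial
        rows.append({"species": species, "garden": garden,
                     "n_initial": n_initial, "n_deaths_retained": n_retained,
                     "MR": mr, "SR": 1.0 - mr, "valid": True})
    return pd.DataFrame(rows)


def compute_ssr(sr_table: pd.DataFrame, native_species: list[str],
                region: str,
                species: list[str] | None = None) -> list[SSRResult]:
    """Standardise ex-situ species' SRs against the native set in a region.

    ``sr_table`` needs columns species, garden, SR. The native mean and the
    sample (n-1) standard deviation are computed over ``native_species``
    with a valid SR in ``region``; at least two are required and sigma must
    be positive.
    """
    sub = sr_table[(sr_table["garden"] == region) & sr_table["SR"].notna()]
    natives = sub[sub["species"].isin(native_species)]
    if len(natives) < 2:
        raise ValueError(
            f"need >= 2 native species with SR in {region!r}, "
            f"got {len(natives)}")
    mu = float(natives["SR"].mean())
    sigma = float(natives["SR"].std(ddof=1))
    if sigma == 0:
        raise ValueError(f"degenerate native SR set in {region!r} (sigma = 0)")
    targets = sub if species is None else sub[sub["species"].isin(species)]
    return [
        SSRResult(species=row["species"], region=region, sr=float(row["SR"]),
                  native_mean=mu, native_sd=sigma,
                  ssr=(float(row["SR"]) - mu) / sigma)
        for _, row in targets.iterrows()
    ]


def classify_sr(sr: float, ssr: float,
                thresholds: SurvivalThresholds | None = None) -> str:
    """Three-level survival class.

    unsuitable if SR < minimal_sr (whatever the SSR); optimal if
    SSR >= -ssr_window (performance within — or above — the native band);
    marginal otherwise.
    """
    t = thresholds or SurvivalThresholds()
    if not (np.isfinite(sr) and np.isfinite(ssr)):
        raise ValueError("sr and ssr must be finite")
    if sr < t.minimal_sr:
        return "unsuitable"
    if ssr >= -t.ssr_window:
        return "optimal"
    return "marginal"


def alignment_verdict(hs_class: str, sr_class: str,
                      species: str = "", region: str = "") -> AlignmentVerdict:
    """Ordinal comparison of HS class vs SR class on
    unsuitable < marginal < optimal."""
    for c in (hs_class, sr_class):
        if c not in CLASS_ORDER:
            raise ValueError(f"unknown class {c!r}; expected one of {HS_CLASSES}")
    d = CLASS_ORDER[hs_class] - CLASS_ORDER[sr_class]
    verdict = "agree" if d == 0 else ("over" if d > 0 else "under")
    return AlignmentVerdict(species, region, hs_class, sr_class, verdict)


def alignment_counts(verdicts: "pd.DataFrame | list[AlignmentVerdict]",
                     by: tuple[str, ...] = ("species",)) -> pd.DataFrame:
    """Cumulative agree/over/under counts across model configurations.

    ``verdicts`` is a list of :class:`AlignmentVerdict` or a data frame with
    at least the ``by`` columns and a ``verdict`` column (one row per
    (model configuration, region) comparison). Counts always satisfy
    agree + over + under = total comparisons per group.
    """
    if not isinstance(verdicts, pd.DataFrame):
        verdicts = pd.DataFrame([v.__dict__ for v in verdicts])
    if len(verdicts) == 0:
        raise ValueError("verdict set is empty")
    counts = (verdicts.groupby(list(by))["verdict"]
              .value_counts().unstack(fill_value=0))
    for col in ("agree", "over", "under"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["agree", "over", "under"]]
    counts["total"] = counts.sum(axis=1)
    return counts.reset_index()


# ---------------------------------------------------------------------------
# packaged worked-example fixture
# ---------------------------------------------------------------------------

def load_survival_fixture() -> pd.DataFrame:
    """Published per-species survival rates at three UK botanic gardens.

    Columns: species, section, native_to, and one SR column per garden
    (KEW, RBGE, WESB); missing entries mean the species is not held (or not
    scorable) at that garden.
    """
    with resources.files("suitsurv.data").joinpath(
            "acer_garden_survival.csv").open() as fh:
        return pd.read_csv(fh)


def fixture_sr_long(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-form (species, section, native_to, garden, SR) view of the
    fixture, NA rows dropped."""
    df = load_survival_fixture() if fixture is None else fixture
    long = df.melt(id_vars=["species", "section", "native_to"],
                   var_name="garden", value_name="SR")
    return long.dropna(subset=["SR"]).reset_index(drop=True)
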
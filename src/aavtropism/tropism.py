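"""Per-variant transduction percentages and nonparametric group comparisons.

The headline imaging statistics are, per (sample, capsid variant): the
percentage of all DAPI nuclei that are GFP+, and the percentage of each
marker-defined cell type (NeuN+ neurons, GFAP+ astrocytes, Iba1+ microglia)
that co-expresses GFP. Marker-class rows with fewer than 30 cells of that
type are flagged excluded so conclusions are never drawn from a handful of
cells. Variants are compared with Kruskal-Wallis tests and Dunn post-hoc
pairwise comparisons adjusted for multiplicity; a supplementary analysis
correlates patient age with transduction efficiency (Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: An image must contain at least this many cells of a marker class for the
#: class percentage to be included in group statistics.
MIN_CELLS_PER_CLASS = 30

TROPISM_COLUMNS = ["patient_id", "sample_id", "section_id", "variant",
                   "denominator_class", "n_denominator", "n_gfp_pos",
                   "percent", "included"]


def compute_tropism(classified: pd.DataFrame, metadata: dict,
                    marker_classes: dict[str, str] | None = None,
                    min_cells: int = MIN_CELLS_PER_CLASS) -> pd.DataFrame:
    """Percent-GFP+ rows for one classified section.

    Parameters
    ----------
    classified
        Output of :func:`aavtropism.thresholds.classify_nuclei`.
    metadata
        Must provide ``sample_id`` and ``variant``; ``patient_id`` and
        ``section_id`` are carried through when present.
    marker_classes
        Map denominator-class name -> boolean flag column, default
        ``{"GFAP": "marker_a_pos", "NeuN": "marker_b_pos"}``.

    The ``all_cells`` denominator is every nucleus; each marker class uses
    the marker-positive nuclei as denominator and those also GFP+ as
    numerator. Marker rows with fewer than ``min_cells`` denominator cells
    get ``included = False``.
    """
    for key in ("sample_id", "variant"):
        if key not in metadata:
            raise ValueError(f"metadata missing required key {key!r}")
    if marker_classes is None:
        marker_classes = {"GFAP": "marker_a_pos", "NeuN": "marker_b_pos"}
    base = {
        "patient_id": metadata.get("patient_id", ""),
        "sample_id": metadata["sample_id"],
        "section_id": metadata.get("section_id", ""),
        "variant": metadata["variant"],
    }
    rows = []
    n_all = len(classified)
    n_pos = int(classified["gfp_pos"].sum()) if n_all else 0
    rows.append({**base, "denominator_class": "all_cells",
                 "n_denominator": n_all, "n_gfp_pos": n_pos,
                 "percent": 100.0 * n_pos / n_all if n_all else np.nan,
                 "included": True})
    for cls, flag in marker_classes.items():
        sub = classified[classified[flag]] if n_all else classified
        n_d = len(sub)
        n_p = int(sub["gfp_pos"].sum()) if n_d else 0
        rows.append({**base, "denominator_class": cls,
                     "n_denominator": n_d, "n_gfp_pos": n_p,
                     "percent": 100.0 * n_p / n_d if n_d else np.nan,
                     "included": n_d >= min_cells})
    return pd.DataFrame(rows, columns=TROPISM_COLUMNS)


def aggregate_sections(rows: pd.DataFrame, policy: str = "mean_sections") -> pd.DataFrame:
    """Collapse per-section rows to one observation per tissue sample.

    Policies
    --------
    ``mean_sections``
        Average the sections' percentages (the two imaged sections of a
        sample contribute equally); counts are summed for bookkeeping.
    ``pool_counts``
        Sum numerators and denominators, then recompute the percentage.
    ``keep_sections``
        Pass-through.

    A sample row is included only if every contributing section row was.
    """
    if policy == "keep_sections":
        return rows.copy()
    if policy not in ("mean_sections", "pool_counts"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    keys = ["patient_id", "sample_id", "variant", "denominator_class"]
    out = []
    for key_vals, grp in rows.groupby(keys, sort=False, dropna=False):
        rec = dict(zip(keys, key_vals))
        rec["section_id"] = "aggregated"
        rec["n_denominator"] = int(grp["n_denominator"].sum())
        rec["n_gfp_pos"] = int(grp["n_gfp_pos"].sum())
        if policy == "mean_sections":
            rec["percent"] = float(grp["percent"].mean())
        else:
            rec["percent"] = (100.0 * rec["n_gfp_pos"] / rec["n_denominator"]
                              if rec["n_denominator"] else np.nan)
        rec["included"] = bool(grp["included"].all())
        out.append(rec)
    return pd.DataFrame(out, columns=TROPISM_COLUMNS)


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise post-hoc comparisons."""

    h_statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted
    letters: dict[str, str]
    alpha: float = 0.05
    adjust_method: str = "bonferroni"


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def dunn_pairwise(samples: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's z statistics on pooled mid-ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie term T = sum(t^3 - t) / (12 (N - 1)) over tied groups of size t.
    Two-sided normal p-values, family-wise adjusted over all pairs.
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    n_tot = pooled.size
    ranks = _midranks(pooled)
    mean_rank = {}
    start = 0
    for g in names:
        n_g = len(samples[g])
        mean_rank[g] = ranks[start:start + n_g].mean()
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    recs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            denom = var_base * (1.0 / len(samples[a]) + 1.0 / len(samples[b]))
            if denom <= 0:
                z = 0.0  # fully tied data: no information, no difference
            else:
                z = (mean_rank[a] - mean_rank[b]) / np.sqrt(denom)
            p = 2.0 * stats.norm.sf(abs(z))
            recs.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    pw = pd.DataFrame(recs)
    if len(pw):
        adjusted = multipletests(pw["p_raw"], method=adjust)[1]
        pw["p_adjusted"] = np.maximum(adjusted, pw["p_raw"])
    return pw


def assign_letters(groups: list[str], pairwise: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact letter display: groups sharing no letter differ significantly.

    Insert-and-absorb algorithm over the significance graph: start with one
    letter containing all groups; for each significantly different pair that
    still shares a letter, split that letter into two (each excluding one
    member of the pair) and drop letters whose group set is a subset of
    another's.
    """
    sig_pairs = {frozenset((r.group_a, r.group_b))
                 for r in pairwise.itertuples() if r.p_adjusted < alpha}
    letters: list[set[str]] = [set(groups)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_letters = []
        for s in letters:
            if a in s and b in s:
                new_letters.extend([s - {a}, s - {b}])
            else:
                new_letters.append(s)
        # absorb subsets
        letters = []
        for s in sorted(new_letters, key=len, reverse=True):
            if s and not any(s <= t for t in letters):
                letters.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in groups:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


def kruskal_dunn(samples: dict[str, list[float]], alpha: float = 0.05,
                 adjust: str = "bonferroni") -> GroupComparisonResult:
    """Kruskal-Wallis across variants with Dunn post-hoc pairwise tests.

    ``samples`` maps group name (capsid variant) to its observations
    (per-sample percentages). Groups with no observations are dropped; at
    least two nonempty groups are required. If every pooled value is
    identical, H = 0 and all p-values are 1.
    """
    clean = {g: np.asarray(v, dtype=float) for g, v in samples.items() if len(v) > 0}
    if len(clean) < 2:
        raise ValueError("need at least two nonempty groups")
    names = list(clean)
    pooled = np.concatenate(list(clean.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*clean.values())
    pw = dunn_pairwise(clean, adjust=adjust)
    letters = assign_letters(names, pw, alpha)
    return GroupComparisonResult(h_statistic=float(h), df=len(clean) - 1,
                                 p_value=float(p), pairwise=pw, letters=letters,
                                 alpha=alpha, adjust_method=adjust)


@dataclass
class AgeCorrelationResult:
    """Spearman correlation of patient age vs percent transduced, per variant."""

    table: pd.DataFrame  # variant, rho, p, n, degenerate
    degenerate_variants: list[str] = field(default_factory=list)


def age_correlation(rows: pd.DataFrame, ages: dict[str, float],
                    denominator_class: str = "all_cells") -> AgeCorrelationResult:
    """Per-variant Spearman rho of (patient age, percent transduced).

    Uses one observation per sample from the aggregated tropism table.
    Variants with fewer than 3 aged samples are skipped; constant-percent
    (or constant-age) variants are flagged degenerate with rho = NaN rather
    than silently reported as 0.
    """
    sub = rows[(rows["denominator_class"] == denominator_class) & rows["included"]]
    recs = []
    degenerate = []
    for variant, grp in sub.groupby("variant", sort=False):
        grp = grp[grp["patient_id"].isin(ages)]
        if len(grp) < 3:
            continue
        x = np.array([ages[p] for p in grp["patient_id"]], dtype=float)
        y = grp["percent"].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            recs.append({"variant": variant, "rho": np.nan, "p": np.nan,
                         "n": len(grp), "degenerate": True})
            degenerate.append(variant)
            continue
        rho, p = stats.spearmanr(x, y)
        recs.append({"variant": variant, "rho": float(rho), "p": float(p),
                     "n": len(grp), "degenerate": False})
    table = pd.DataFrame(recs, columns=["variant", "rho", "p", "n", "degenerate"])
    return AgeCorrelationResult(table=table, degenerate_variants=degenerate)


def plot_tropism_bars(rows: pd.DataFrame, path,
                      denominator_class: str = "all_cells",
                      letters: dict[str, str] | None = None) -> None:
    """Bar chart of mean +/- SEM percent transduced per variant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = rows[(rows["denominator_class"] == denominator_class) & rows["included"]]
    stats_tab = sub.groupby("variant")["percent"].agg(["mean", "sem", "count"])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(stats_tab.index, stats_tab["mean"], yerr=stats_tab["sem"].fillna(0.0),
           capsize=3, color="#4C72B0")
    if letters:
        for i, v in enumerate(stats_tab.index):
            ax.text(i, stats_tab.loc[v, "mean"] + 2, letters.get(v, ""),
                    ha="center", fontsize=9)
    ax.set_ylabel(f"% GFP+ ({denominator_class})")
    ax.set_xlabel("AAV capsid variant")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
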
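"""Taxonomy-sweeping differential abundance and responder rules.

Each taxon's reads are modelled as binomial successes out of the sample's
total reads, with a one-factor logistic GLM over the soil x treatment
groups.  All pairwise group contrasts are tested on the logit scale with
both unadjusted p-values and single-step (max-|z|, Tukey-style) adjusted
p-values from the joint normal distribution of the contrasts.  Groups with
zero (or full) pooled counts make the Wald test invalid (complete
separation); contrasts touching such a group fall back to a Fisher exact
test on pooled counts and are flagged.

On top of the sweep sit the two responder rules:

* enriched taxa: spiked > control with unadjusted p below alpha (0.05),
  evaluated per soil; "common" responders are enriched in every soil;
* diminished OTUs: control share at least 5x the average detected OTU's
  share and never detected in the corresponding spiked samples (rule 1),
  or at least 4x the average and significantly higher in control (rule 2).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .otu_report import OtuTable, SampleGroups

OTU_RANK = "otu"
DEFAULT_RANKS = ("phylum", "class", "order", "family", "genus", OTU_RANK)


class SkipTaxon(ValueError):
    """The taxon has no reads at all; no test is possible."""


@dataclass
class GroupGLMFit:
    """Fitted one-factor binomial logistic model for one taxon."""

    groups: list[str]
    params: pd.Series | None  # logit-scale group means (non-separated groups)
    cov: pd.DataFrame | None
    pooled_y: pd.Series  # successes per group
    pooled_n: pd.Series  # trials per group
    separated: list[str]  # groups with 0 or all successes (Wald invalid)


def fit_group_glm(
    y: np.ndarray, n: np.ndarray, group_labels: pd.Series
) -> GroupGLMFit:
    """Fit the binomial logistic group model for one taxon.

    ``y``/``n`` are per-sample taxon reads and depths aligned with
    ``group_labels`` (sample -> group).  Requires at least two groups with
    two samples each.  Raises :class:`SkipTaxon` if the taxon has no reads.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(y > n):
        raise ValueError("taxon reads exceed sample depth")
    labels = pd.Series(group_labels).astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    if y.sum() == 0:
        raise SkipTaxon("taxon has zero reads in all samples")
    pooled_y = pd.Series({g: y[labels.values == g].sum() for g in groups})
    pooled_n = pd.Series({g: n[labels.values == g].sum() for g in groups})
    separated = [
        g for g in groups if pooled_y[g] == 0 or pooled_y[g] == pooled_n[g]
    ]
    fit_groups = [g for g in groups if g not in separated]
    params = cov = None
    if len(fit_groups) >= 2:
        mask = labels.isin(fit_groups).to_numpy()
        exog = pd.get_dummies(labels[mask]).astype(float)[fit_groups]
        endog = np.column_stack([y[mask], n[mask] - y[mask]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog.to_numpy(), family=sm.families.Binomial()).fit()
        params = pd.Series(res.params, index=fit_groups)
        cov = pd.DataFrame(res.cov_params(), index=fit_groups, columns=fit_groups)
    return GroupGLMFit(
        groups=groups,
        params=params,
        cov=cov,
        pooled_y=pooled_y,
        pooled_n=pooled_n,
        separated=separated,
    )


_ADJUST_DRAWS = 20_000
_ADJUST_SEED = 20120821  # fixed: the adjustment is a deterministic numerical step


def _single_step_adjust(z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step (max-|z|) adjusted p-values under the joint normal law of
    the contrasts — the multiplicity adjustment behind Tukey-style all-pairs
    comparisons in GLMs.  The max-|Z| reference distribution is evaluated by
    a fixed-seed Monte-Carlo sample of the joint normal (standard error of
    an adjusted p near 0.05 is about 0.0015)."""
    m = len(z)
    if m == 1:
        return np.array([2 * stats.norm.sf(abs(z[0]))])
    corr = np.clip(np.asarray(corr, dtype=float), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    # PSD square root via eigendecomposition (contrast matrices are singular)
    w, v = np.linalg.eigh(corr)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(_ADJUST_SEED)
    draws = rng.standard_normal((_ADJUST_DRAWS, m)) @ root.T
    max_abs = np.sort(np.abs(draws).max(axis=1))
    out = np.empty(m)
    for k, zk in enumerate(np.abs(z)):
        if not np.isfinite(zk):
            out[k] = np.nan
            continue
        # P(max |Z| >= zk) with >= via searchsorted on the sorted sample
        out[k] = 1.0 - np.searchsorted(max_abs, zk, side="left") / _ADJUST_DRAWS
    return out


def tukey_contrasts(fit: GroupGLMFit) -> pd.DataFrame:
    """All pairwise group contrasts for one fitted taxon.

    Wald z-tests on the logit scale with single-step adjusted p-values for
    contrasts among non-separated groups; Fisher exact tests on pooled
    counts (flagged ``method='fisher'``, Bonferroni-adjusted) for contrasts
    touching a separated group.  Estimates are log-odds differences
    (group_b minus group_a, groups in sorted order; Haldane 0.5 correction
    on the Fisher path).
    """
    pairs = list(itertools.combinations(fit.groups, 2))
    wald_pairs = [
        (a, b) for a, b in pairs if a not in fit.separated and b not in fit.separated
    ]
    rows: dict[tuple[str, str], dict] = {}
    if wald_pairs and fit.params is not None:
        fit_groups = list(fit.params.index)
        L = np.zeros((len(wald_pairs), len(fit_groups)))
        for k, (a, b) in enumerate(wald_pairs):
            L[k, fit_groups.index(b)] = 1.0
            L[k, fit_groups.index(a)] = -1.0
        est = L @ fit.params.to_numpy()
        V = L @ fit.cov.to_numpy() @ L.T
        sd = np.sqrt(np.diag(V))
        z = est / sd
        corr = V / np.outer(sd, sd)
        p_unadj = 2 * stats.norm.sf(np.abs(z))
        p_adj = _single_step_adjust(z, corr)
        for k, (a, b) in enumerate(wald_pairs):
            rows[(a, b)] = {
                "estimate": float(est[k]),
                "z": float(z[k]),
                "p": float(p_unadj[k]),
                "p_adj": float(p_adj[k]),
                "method": "wald",
            }
    m_total = len(pairs)
    for a, b in pairs:
        if (a, b) in rows:
            continue
        ya, na = fit.pooled_y[a], fit.pooled_n[a]
        yb, nb = fit.pooled_y[b], fit.pooled_n[b]
        table = np.array([[ya, na - ya], [yb, nb - yb]])
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        est = float(
            np.log((yb + 0.5) / (nb - yb + 0.5)) - np.log((ya + 0.5) / (na - ya + 0.5))
        )
        rows[(a, b)] = {
            "estimate": est,
            "z": np.nan,
            "p": p,
            "p_adj": min(1.0, p * m_total),
            "method": "fisher",
        }
    out = []
    for a, b in pairs:
        r = rows[(a, b)]
        prop_a = fit.pooled_y[a] / fit.pooled_n[a]
        prop_b = fit.pooled_y[b] / fit.pooled_n[b]
        direction = b if prop_b > prop_a else (a if prop_a > prop_b else "tie")
        out.append({"group_a": a, "group_b": b, **r, "direction": direction})
    df = pd.DataFrame(out)
    df["p_adj"] = np.maximum(df["p_adj"], df["p"])  # adjusted never below raw
    return df


# -- taxonomy sweep ------------------------------------------------------------


def sweep_taxonomy(
    table: OtuTable,
    groups: SampleGroups,
    ranks: tuple[str, ...] = DEFAULT_RANKS,
    compute_adjusted: bool = True,
) -> pd.DataFrame:
    """Test every taxon at every rank (phylum ... genus, then raw OTUs).

    Returns a tidy frame with one row per taxon x group pair, carrying the
    log-odds estimate, z, unadjusted p, single-step adjusted p, test method
    (``wald`` or the separation fallback ``fisher``), direction, per-group
    mean +- sd relative abundance in percent, and Benjamini-Hochberg
    q-values (``q_bh``) computed per rank across all taxa and contrasts as
    a modern companion to the unadjusted decision rule.
    """
    groups.check_samples(table.sample_ids)
    depths = table.depths().to_numpy(dtype=float)
    labels = pd.Series(
        [groups.group_of(s) for s in table.sample_ids], index=table.sample_ids
    )
    frames = []
    for rank in ranks:
        sub = table if rank == OTU_RANK else table.aggregate_at_rank(rank)
        counts = sub.counts.to_numpy(dtype=float)
        rel = counts / depths[None, :] * 100.0
        for i, taxon in enumerate(sub.counts.index):
            try:
                fit = fit_group_glm(counts[i], depths, labels)
            except SkipTaxon:
                continue
            con = tukey_contrasts(fit)
            if not compute_adjusted:
                con["p_adj"] = np.nan
            stats_by_group = {
                g: (
                    float(np.mean(rel[i, labels.values == g])),
                    float(np.std(rel[i, labels.values == g], ddof=1)),
                )
                for g in fit.groups
            }
            con.insert(0, "rank", rank)
            con.insert(1, "taxon", str(taxon))
            con["mean_a"] = [stats_by_group[a][0] for a in con["group_a"]]
            con["sd_a"] = [stats_by_group[a][1] for a in con["group_a"]]
            con["mean_b"] = [stats_by_group[b][0] for b in con["group_b"]]
            con["sd_b"] = [stats_by_group[b][1] for b in con["group_b"]]
            frames.append(con)
    result = pd.concat(frames, ignore_index=True)
    result["q_bh"] = np.nan
    for rank in result["rank"].unique():
        mask = result["rank"] == rank
        result.loc[mask, "q_bh"] = multipletests(
            result.loc[mask, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return result


# -- responder rules -----------------------------------------------------------


@dataclass
class ResponderReport:
    """Enriched taxa and diminished OTUs, per soil, with rule provenance."""

    alpha: float
    enriched: dict[str, pd.DataFrame] = field(default_factory=dict)
    common_enriched: pd.DataFrame | None = None
    diminished: dict[str, pd.DataFrame] = field(default_factory=dict)


def enriched_taxa(
    sweep: pd.DataFrame,
    groups: SampleGroups,
    alpha: float = 0.05,
    soils: list[str] | None = None,
) -> ResponderReport:
    """Taxa significantly enriched in the spiked soil(s).

    A taxon is enriched in a soil when its spiked-vs-control contrast for
    that soil has the spiked direction and unadjusted p < alpha.  Commonly
    enriched taxa are those enriched in every analyzed soil.
    """
    soils = soils or groups.soils
    report = ResponderReport(alpha=alpha)
    keys_per_soil = []
    for soil in soils:
        control = f"{soil}:{SampleGroups.CONTROL}"
        spiked = f"{soil}:{SampleGroups.SPIKED}"
        pair = sweep[
            ((sweep["group_a"] == control) & (sweep["group_b"] == spiked))
            | ((sweep["group_a"] == spiked) & (sweep["group_b"] == control))
        ]
        hits = pair[(pair["direction"] == spiked) & (pair["p"] < alpha)].copy()
        hits["soil"] = soil
        report.enriched[soil] = hits.reset_index(drop=True)
        keys_per_soil.append(set(zip(hits["rank"], hits["taxon"])))
    common = set.intersection(*keys_per_soil) if keys_per_soil else set()
    rows = [{"rank": r, "taxon": t} for r, t in sorted(common)]
    report.common_enriched = pd.DataFrame(rows, columns=["rank", "taxon"])
    return report


def diminished_otus(
    table: OtuTable,
    groups: SampleGroups,
    alpha: float = 0.05,
    detection: str = "share",
) -> ResponderReport:
    """OTUs numerically reduced in the spiked soils, by two stringent rules.

    Per soil, the "average detection" of an OTU is the mean share of the
    OTUs detected in that soil's control samples, i.e. 1/S_control with the
    default share-based reading (``detection='prevalence'`` instead uses
    the fraction of control samples in which the OTU appears).  Then

    * rule 1: control share >= 5x average AND zero reads in every
      corresponding spiked sample;
    * rule 2: control share >= 4x average AND control > spiked with
      p < alpha in the OTU-level contrast (Wald, or Fisher on pooled counts
      when the spiked group is all-zero).
    """
    if detection not in ("share", "prevalence"):
        raise ValueError("detection must be 'share' or 'prevalence'")
    groups.check_samples(table.sample_ids)
    depths = table.depths()
    report = ResponderReport(alpha=alpha)
    for soil in groups.soils:
        control_ids = groups.samples_for(soil, SampleGroups.CONTROL)
        spiked_ids = groups.samples_for(soil, SampleGroups.SPIKED)
        if len(control_ids) < 2 or len(spiked_ids) < 2:
            raise ValueError(
                f"soil {soil!r} needs >= 2 control and >= 2 spiked samples"
            )
        c_total = table.counts[control_ids].sum(axis=1)
        s_total = table.counts[spiked_ids].sum(axis=1)
        detected = c_total > 0
        s_ctl = int(detected.sum())
        if s_ctl == 0:
            report.diminished[soil] = pd.DataFrame(
                columns=["otu_id", "rule", "control_share", "average", "p"]
            )
            continue
        if detection == "share":
            value = c_total / float(depths[control_ids].sum())
            average = 1.0 / s_ctl
        else:
            prev = (table.counts[control_ids] > 0).mean(axis=1)
            value = prev
            average = float(prev[detected].mean())
        labels = pd.Series(
            [groups.group_of(s) for s in control_ids + spiked_ids],
            index=control_ids + spiked_ids,
        )
        sub_depths = depths[control_ids + spiked_ids].to_numpy(dtype=float)
        rows = []
        candidates = table.counts.index[detected & (value >= 4.0 * average)]
        for otu in candidates:
            share = float(value[otu])
            if share >= 5.0 * average and s_total[otu] == 0:
                rows.append(
                    {
                        "otu_id": otu,
                        "rule": "rule1_absent",
                        "control_share": share,
                        "average": average,
                        "p": np.nan,
                    }
                )
                continue
            y = table.counts.loc[otu, control_ids + spiked_ids].to_numpy(dtype=float)
            try:
                fit = fit_group_glm(y, sub_depths, labels)
            except SkipTaxon:
                continue
            con = tukey_contrasts(fit).iloc[0]
            control_grp = f"{soil}:{SampleGroups.CONTROL}"
            if con["direction"] == control_grp and con["p"] < alpha:
                rows.append(
                    {
                        "otu_id": otu,
                        "rule": "rule2_significant",
                        "control_share": share,
                        "average": average,
                        "p": float(con["p"]),
                    }
                )
        report.diminished[soil] = pd.DataFrame(
            rows, columns=["otu_id", "rule", "control_share", "average", "p"]
        )
    return report
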
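"""Analysis pipeline: community table in, result tables out.

Given a long-format community table (one row per flask × species) the
pipeline computes, at both local (patch) and metacommunity scales:

* biovolume / RUE / evenness metric tables (ln transforms included);
* the additive partition of the net biodiversity effect, with delta-RUE and
  delta-evenness, per replicate;
* one-sample t tests of each effect against zero (grouped by phosphorus
  level, and additionally by N:P ratio at the local scale);
* factorial ANOVA tables — mixture-only responses against phosphorus supply
  (and N:P locally), and all-composition responses against supply ×
  composition (× N:P locally).  Local-scale ANOVAs apply the conservative
  error-df / 3 adjustment; metacommunity-scale ANOVAs use the actual df,
  since metacommunities are independent units;
* RUE–evenness correlations on raw values and on treatment residuals.

Replicate pairing for observed-vs-expected statistics: mixture replicate r
is compared against expectations built from monoculture replicates r of the
same supply cell, so each phosphorus level contributes one delta per
replicate and t tests have n − 1 = 2 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anova import AnovaTable, balanced_anova, pearson_r, treatment_residuals
from .config import MIXTURE, ExperimentConfig
from .metrics import (
    metacommunity_totals,
    pielou_evenness,
    rue_local,
    rue_metacommunity,
)
from .partition import (
    additive_partition,
    delta_evenness,
    delta_rue,
    one_sample_t,
)

__all__ = [
    "AnalysisResult",
    "local_metrics_table",
    "metacommunity_metrics_table",
    "partition_table",
    "ttest_table",
    "analyze",
]

EFFECT_COLUMNS = ("net", "complementarity", "selection", "delta_rue", "delta_even")


def _sample(group: pd.DataFrame) -> dict[str, float]:
    return dict(zip(group["species"], group["biovolume_um3_per_ml"]))


def local_metrics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-flask totals, RUE and evenness (evenness for mixtures only)."""
    keys = [
        "metacommunity_id",
        "patch_id",
        "composition",
        "p_sup_level",
        "p_sup",
        "np_ratio",
        "replicate",
    ]
    rows = []
    for key_vals, grp in table.groupby(keys, sort=False):
        rec = dict(zip(keys, key_vals))
        total = float(grp["biovolume_um3_per_ml"].sum())
        rec["total_biovolume"] = total
        rec["rue"] = rue_local(total, rec["p_sup"])
        rec["ln_biovolume"] = math.log(total) if total > 0 else np.nan
        rec["ln_rue"] = math.log(rec["rue"]) if rec["rue"] > 0 else np.nan
        rec["evenness"] = (
            pielou_evenness(_sample(grp)) if rec["composition"] == MIXTURE else np.nan
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def metacommunity_metrics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metacommunity mean biovolume, regional RUE, pooled evenness."""
    keys = ["metacommunity_id", "composition", "p_sup_level", "p_sup", "replicate"]
    rows = []
    for key_vals, grp in table.groupby(keys, sort=False):
        rec = dict(zip(keys, key_vals))
        patches = [_sample(g) for _, g in grp.groupby("patch_id", sort=False)]
        totals = [sum(p.values()) for p in patches]
        pooled = metacommunity_totals(patches)
        mean_total = float(np.mean(totals))
        rec["mean_biovolume"] = mean_total
        rec["rue"] = rue_metacommunity(totals, rec["p_sup"])
        rec["ln_biovolume"] = math.log(mean_total) if mean_total > 0 else np.nan
        rec["ln_rue"] = math.log(rec["rue"]) if rec["rue"] > 0 else np.nan
        rec["evenness"] = (
            pielou_evenness(pooled) if rec["composition"] == MIXTURE else np.nan
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def _mc_species_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metacommunity per-species biovolume averaged over its 3 patches."""
    keys = ["metacommunity_id", "composition", "p_sup_level", "p_sup", "replicate"]
    return (
        table.groupby(keys + ["species"], sort=False)["biovolume_um3_per_ml"]
        .mean()
        .reset_index()
    )


def partition_table(table: pd.DataFrame, scale: str = "metacommunity") -> pd.DataFrame:
    """Additive partition + deltas per replicate at the requested scale.

    ``scale`` is 'metacommunity' (monoculture yields averaged over the three
    patches of the monoculture metacommunity) or 'local' (patch matched by
    N:P ratio).  Only phosphorus levels at which all monocultures exist
    contribute rows; a monoculture-only or mixture-only table yields an
    empty frame.
    """
    if scale == "metacommunity":
        data = _mc_species_means(table)
        group_keys = ["p_sup_level", "p_sup", "replicate"]
    elif scale == "local":
        data = table
        group_keys = ["p_sup_level", "p_sup", "np_ratio", "replicate"]
    else:
        raise ValueError(f"unknown scale {scale!r}")

    species = sorted(set(data["species"]))
    rows = []
    for key_vals, grp in data.groupby(group_keys, sort=False):
        rec = dict(zip(group_keys, key_vals))
        mix = grp[grp["composition"] == MIXTURE]
        if mix.empty:
            continue
        mono_yields = {}
        for sp in species:
            mono = grp[(grp["composition"] == sp) & (grp["species"] == sp)]
            if mono.empty:
                mono_yields = None
                break
            mono_yields[sp] = float(mono["biovolume_um3_per_ml"].sum())
        if mono_yields is None:
            continue
        mix_sample = dict(zip(mix["species"], mix["biovolume_um3_per_ml"]))
        part = additive_partition(mix_sample, mono_yields)
        p_sup = rec["p_sup"]
        mono_rues = {sp: m / p_sup for sp, m in mono_yields.items()}
        rec.update(
            net=part.net,
            complementarity=part.complementarity,
            selection=part.selection,
            y_obs=part.y_obs,
            y_exp=part.y_exp,
            delta_rue=delta_rue(part.y_obs / p_sup, mono_rues),
            delta_even=delta_evenness(mix_sample, mono_yields),
        )
        rows.append(rec)
    columns = group_keys + ["net", "complementarity", "selection", "y_obs", "y_exp",
                            "delta_rue", "delta_even"]
    return pd.DataFrame(rows, columns=columns)


def ttest_table(partitions: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """One-sample t tests of each effect column against zero, per group."""
    rows = []
    if partitions.empty:
        return pd.DataFrame(
            columns=list(by) + [f"{e}_{s}" for e in EFFECT_COLUMNS for s in ("t", "p")]
        )
    for key_vals, grp in partitions.groupby(list(by), sort=False):
        rec = dict(zip(by, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec["n"] = len(grp)
        for effect in EFFECT_COLUMNS:
            vals = grp[effect].dropna()
            try:
                res = one_sample_t(vals)
                rec[f"{effect}_t"] = res.t
                rec[f"{effect}_p"] = res.p
            except ValueError:
                rec[f"{effect}_t"] = np.nan
                rec[f"{effect}_p"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class AnalysisResult:
    """All result tables from one analysis run."""

    local_metrics: pd.DataFrame
    mc_metrics: pd.DataFrame
    local_partition: pd.DataFrame
    mc_partition: pd.DataFrame
    local_ttests: pd.DataFrame
    mc_ttests: pd.DataFrame
    anova: dict[str, AnovaTable] = field(default_factory=dict)
    correlations: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "local_metrics": self.local_metrics,
            "mc_metrics": self.mc_metrics,
            "local_partition": self.local_partition,
            "mc_partition": self.mc_partition,
            "local_ttests": self.local_ttests,
            "mc_ttests": self.mc_ttests,
        }
        for name, tab in self.anova.items():
            out[f"anova_{name}"] = tab.to_frame()
        if self.correlations is not None:
            out["correlations"] = self.correlations
        return out


def _anova_tables(
    local: pd.DataFrame, mc: pd.DataFrame
) -> dict[str, AnovaTable]:
    """Assemble the standard ANOVA set; skips tables the data cannot support."""
    out: dict[str, AnovaTable] = {}

    def try_anova(name, data, response, factors, adjustment):
        sub = data.dropna(subset=[response])
        if sub.empty:
            return
        try:
            out[name] = balanced_anova(
                sub, response, factors, df_adjustment=adjustment
            )
        except ValueError:
            pass

    mix_mc = mc[mc["composition"] == MIXTURE]
    mix_local = local[local["composition"] == MIXTURE]
    for resp in ("ln_biovolume", "ln_rue", "evenness"):
        try_anova(f"mc_mixture_{resp}", mix_mc, resp, ["p_sup_level"], 1.0)
        try_anova(
            f"local_mixture_{resp}",
            mix_local,
            resp,
            ["p_sup_level", "np_ratio"],
            3.0,
        )

    # Composition analyses use only supply levels where every composition ran.
    def full_levels(data):
        n_comp = data["composition"].nunique()
        counts = data.groupby("p_sup_level", observed=True)["composition"].nunique()
        return counts[counts == n_comp].index

    lv_mc = full_levels(mc)
    lv_local = full_levels(local)
    comp_mc = mc[mc["p_sup_level"].isin(lv_mc)]
    comp_local = local[local["p_sup_level"].isin(lv_local)]
    for resp in ("ln_biovolume", "ln_rue"):
        try_anova(
            f"mc_composition_{resp}",
            comp_mc,
            resp,
            ["p_sup_level", "composition"],
            1.0,
        )
        try_anova(
            f"local_composition_{resp}",
            comp_local,
            resp,
            ["p_sup_level", "np_ratio", "composition"],
            3.0,
        )
    return out


def _correlation_table(local: pd.DataFrame, mc: pd.DataFrame) -> pd.DataFrame:
    """RUE–evenness correlations (mixtures), raw and treatment residuals."""
    rows = []

    def corr(name, data, factors):
        sub = data.dropna(subset=["evenness", "ln_rue"]).copy()
        if len(sub) < 3:
            return
        try:
            raw = pearson_r(sub["evenness"], sub["ln_rue"])
            rows.append(
                {"scale": name, "kind": "raw", "r": raw.r, "p": raw.p, "n": raw.n}
            )
            res_x = treatment_residuals(sub, "evenness", factors)
            res_y = treatment_residuals(sub, "ln_rue", factors)
            res = pearson_r(res_x, res_y)
            rows.append(
                {"scale": name, "kind": "residual", "r": res.r, "p": res.p, "n": res.n}
            )
        except ValueError:
            pass

    corr("metacommunity", mc[mc["composition"] == MIXTURE], ["p_sup_level"])
    corr(
        "local",
        local[local["composition"] == MIXTURE],
        ["p_sup_level", "np_ratio"],
    )
    return pd.DataFrame(rows, columns=["scale", "kind", "r", "p", "n"])


def analyze(
    table: pd.DataFrame, config: ExperimentConfig | None = None
) -> AnalysisResult:
    """Run the full analysis pipeline on a community table."""
    local = local_metrics_table(table)
    mc = metacommunity_metrics_table(table)
    local_part = partition_table(table, scale="local")
    mc_part = partition_table(table, scale="metacommunity")
    result = AnalysisResult(
        local_metrics=local,
        mc_metrics=mc,
        local_partition=local_part,
        mc_partition=mc_part,
        local_ttests=ttest_table(local_part, by=["p_sup_level", "np_ratio"]),
        mc_ttests=ttest_table(mc_part, by=["p_sup_level"]),
        anova=_anova_tables(local, mc),
        correlations=_correlation_table(local, mc),
    )
    return result
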
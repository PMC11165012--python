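"""Plate-level screening statistics and hit calling.

The screen readout is a long well table (plate, well, compound, role,
replicate, Ki67/HuC-D positivity ratios, nuclei count). Analysis follows
the standard high-content screening flow: per-plate median normalization
on DMSO control wells, Z'-factor plate QC against the positive control,
a two-metric 3-SD hit window around the DMSO distribution with a live-cell
toxicity cutoff, replicate concordance, and dose-response specificity
selection via exact permutation Spearman trend tests. ΔΔCt quantification
and Welch's t-test round out the summary statistics used by the study
design this package reimplements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError, WellRole

METRICS = ("ki67_ratio", "hucd_ratio")


# ------------------------------------------------------------ normalization


@dataclass
class NormalizedScreen:
    """Well table with plate-DMSO-median normalized metric columns."""

    table: pd.DataFrame            # adds <metric>_norm columns
    mode: str                      # "centered" (subtract) or "fold" (divide)
    excluded_plates: list = field(default_factory=list)
    qc: pd.DataFrame | None = None  # filled by plate_qc

    def passing_table(self) -> pd.DataFrame:
        if self.qc is None:
            return self.table
        passing = set(self.qc.loc[self.qc["pass"], "plate"])
        return self.table[self.table["plate"].isin(passing)]


def median_normalize(table: pd.DataFrame, mode: str = "centered",
                     min_dmso_wells: int = 8) -> NormalizedScreen:
    """Normalize each plate's metrics by its DMSO-well median.

    Centered mode subtracts the per-plate DMSO median (fold mode divides).
    Plates with fewer than ``min_dmso_wells`` DMSO wells are flagged and
    excluded. Raw columns are preserved.
    """
    if mode not in ("centered", "fold"):
        raise ConfigError(f"unknown normalization mode {mode!r}")
    out = table.copy()
    excluded = []
    for metric in METRICS:
        out[metric + "_norm"] = np.nan
    for plate, grp in table.groupby("plate"):
        dmso = grp[grp["role"] == WellRole.DMSO]
        if len(dmso) < min_dmso_wells:
            excluded.append(plate)
            continue
        idx = grp.index
        for metric in METRICS:
            med = dmso[metric].median()
            if mode == "centered":
                out.loc[idx, metric + "_norm"] = grp[metric] - med
            else:
                out.loc[idx, metric + "_norm"] = grp[metric] / med if med else np.nan
    if excluded:
        out = out[~out["plate"].isin(excluded)]
    return NormalizedScreen(out, mode, excluded)


# ------------------------------------------------------------------- QC


def z_prime(pos, neg) -> float:
    """Z' factor: 1 - 3(SD_pos + SD_neg) / |mean_pos - mean_neg| (sample SDs).

    NaN (plate fails) when the control means coincide.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 wells per control group")
    delta = abs(pos.mean() - neg.mean())
    if delta == 0:
        return float("nan")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / delta


def plate_qc(screen: NormalizedScreen, z_min: float = 0.2) -> NormalizedScreen:
    """Per-plate Z' between positive-control and DMSO wells on both metrics.

    A plate passes iff both metrics' Z' >= ``z_min`` (plates below the
    cutoff are discarded from hit calling, boundary inclusive).
    """
    rows = []
    for plate, grp in screen.table.groupby("plate"):
        pos = grp[grp["role"] == WellRole.POSITIVE]
        neg = grp[grp["role"] == WellRole.DMSO]
        rec = {"plate": plate}
        ok = True
        for metric in METRICS:
            col = metric + "_norm"
            try:
                z = z_prime(pos[col], neg[col])
            except ValueError:
                z = float("nan")
            rec["z_prime_" + metric.split("_")[0]] = z
            ok = ok and np.isfinite(z) and z >= z_min
        rec["pass"] = ok
        rows.append(rec)
    screen.qc = pd.DataFrame(rows)
    return screen


# --------------------------------------------------------------- hit calling


@dataclass
class HitCallResult:
    per_compound: pd.DataFrame  # mean normalized metrics, nuclei, flags
    thresholds: dict
    excluded_compounds: list

    @property
    def hits(self) -> list:
        return sorted(self.per_compound.loc[self.per_compound["hit"], "compound"])

    @property
    def n_hits(self) -> int:
        return int(self.per_compound["hit"].sum())


def call_hits(screen: NormalizedScreen, k: float = 3.0,
              toxicity_cutoff: float = 2000, sd_scope: str = "global") -> HitCallResult:
    """3-SD two-metric quadrant hit rule with live-count toxicity exclusion.

    Replicate wells per compound are averaged first. The DMSO window is
    the pooled normalized DMSO median +/- k x SD across passing plates
    (``sd_scope='per_plate'`` averages per-plate SDs instead). Hit: mean
    normalized Ki67 above the upper window AND mean normalized HuC/D below
    the lower window. Toxic: mean raw nuclei count strictly below the
    cutoff; toxic compounds are removed from the hit set.
    """
    df = screen.passing_table()
    dmso = df[df["role"] == WellRole.DMSO]
    if dmso.empty:
        raise ConfigError("no DMSO wells on passing plates")
    stats_ = {}
    for metric in METRICS:
        col = metric + "_norm"
        med = float(dmso[col].median())
        if sd_scope == "global":
            sd = float(dmso[col].std(ddof=1))
        elif sd_scope == "per_plate":
            sd = float(dmso.groupby("plate")[col].std(ddof=1).mean())
        else:
            raise ConfigError(f"unknown sd_scope {sd_scope!r}")
        stats_[metric] = (med, sd)

    comp = df[df["role"] == WellRole.COMPOUND]
    agg = comp.groupby("compound").agg(
        ki67_norm=("ki67_ratio_norm", "mean"),
        hucd_norm=("hucd_ratio_norm", "mean"),
        nuclei=("nuclei_count", "mean"),
        n_replicates=("replicate", "nunique"),
    ).reset_index()
    excluded = sorted(agg.loc[agg["n_replicates"] < 1, "compound"])
    agg = agg[agg["n_replicates"] >= 1].copy()

    ki_med, ki_sd = stats_["ki67_ratio"]
    hu_med, hu_sd = stats_["hucd_ratio"]
    agg["toxic"] = agg["nuclei"] < toxicity_cutoff
    agg["in_window"] = (agg["ki67_norm"] > ki_med + k * ki_sd) & \
                       (agg["hucd_norm"] < hu_med - k * hu_sd)
    agg["hit"] = agg["in_window"] & ~agg["toxic"]
    thresholds = {
        "k": k, "toxicity_cutoff": toxicity_cutoff, "sd_scope": sd_scope,
        "median_ki67": ki_med, "sd_ki67": ki_sd,
        "median_hucd": hu_med, "sd_hucd": hu_sd,
    }
    return HitCallResult(agg, thresholds, excluded)


def replicate_concordance(screen: NormalizedScreen) -> dict:
    """Pearson r between replicate-1 and replicate-2 normalized metrics
    across compounds (pairs with a missing mate are dropped)."""
    comp = screen.passing_table()
    comp = comp[comp["role"] == WellRole.COMPOUND]
    out = {}
    for metric, key in (("ki67_ratio", "pearson_ki67"), ("hucd_ratio", "pearson_hucd")):
        wide = comp.pivot_table(index="compound", columns="replicate",
                                values=metric + "_norm", aggfunc="mean")
        if wide.shape[1] < 2:
            out[key] = float("nan")
            continue
        pair = wide.iloc[:, :2].dropna()
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        out[key] = float(np.corrcoef(x, y)[0, 1]) if len(pair) > 1 else float("nan")
    return out


# ----------------------------------------------------------- dose response


@lru_cache(maxsize=8)
def _rank_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=float)


def _pearson_rows(mat: np.ndarray, y: np.ndarray) -> np.ndarray:
    mc = mat - mat.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((mc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mc @ yc) / denom


@dataclass
class TrendResult:
    rho: float
    p: float
    direction: str
    significant: bool
    n_doses: int


def dose_trend(doses, responses, direction: str = "increasing",
               alpha: float = 0.05, min_doses: int = 4) -> TrendResult:
    """Spearman correlation of response vs log10(dose) with an exact
    one-sided permutation p-value in the required direction.

    For <= 8 doses the permutation null is enumerated exhaustively; a
    constant series has rho = 0 and is never significant.
    """
    doses = np.asarray(doses, float)
    responses = np.asarray(responses, float)
    if direction not in ("increasing", "decreasing"):
        raise ConfigError(f"unknown direction {direction!r}")
    n = len(doses)
    if n < min_doses:
        raise ValueError(f"need at least {min_doses} non-toxic doses, got {n}")
    x = stats.rankdata(np.log10(doses))
    y = stats.rankdata(responses)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return TrendResult(0.0, 1.0, direction, False, n)
    rho = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if direction == "increasing" else -1.0
    if n <= 8:
        # permute rank positions of the observed (possibly tied) response ranks
        perms = _rank_permutations(n)
        ranks_mat = y[perms.astype(int)]
        rhos = _pearson_rows(ranks_mat, x)
        p = float(np.mean(sign * rhos >= sign * rho - 1e-12))
    else:
        res = stats.spearmanr(x, y, alternative="greater" if sign > 0 else "less")
        p = float(res.pvalue)
    return TrendResult(rho, p, direction, bool(p < alpha), n)


def _dose_series(grp: pd.DataFrame, metric: str, toxicity_cutoff: float):
    """Per-dose replicate means with toxic doses removed."""
    per_dose = grp.groupby("dose_um").agg(
        resp=(metric, "mean"), nuclei=("nuclei_count", "mean")).reset_index()
    ok = per_dose[per_dose["nuclei"] >= toxicity_cutoff]
    return ok["dose_um"].to_numpy(), ok["resp"].to_numpy()


def select_specific_compounds(dose_table: pd.DataFrame, mutant_line: str,
                              control_line: str, alpha: float = 0.05,
                              toxicity_cutoff: float = 2000,
                              min_doses: int = 4) -> pd.DataFrame:
    """Apply the three-part selection: dose-dependent proliferation increase,
    dose-dependent differentiation decrease, and mutant-line specificity.

    A compound is proliferation-specific when its Ki67 trend is
    significantly increasing in the mutant line and not significantly
    increasing in the control line; differentiation-specific analogously
    with decreasing HuC/D; ``selected`` requires both. Toxic doses (mean
    nuclei below the cutoff) are dropped before trend testing.
    """
    rows = []
    for compound, cgrp in dose_table.groupby("compound"):
        rec = {"compound": compound}
        trends = {}
        for line, tag in ((mutant_line, "mutant"), (control_line, "control")):
            grp = cgrp[cgrp["cell_line"] == line]
            for metric, direction, name in (
                ("ki67_ratio", "increasing", "prolif"),
                ("hucd_ratio", "decreasing", "diff"),
            ):
                key = f"{name}_{tag}"
                if grp.empty:
                    trends[key] = None
                    continue
                d, r = _dose_series(grp, metric, toxicity_cutoff)
                try:
                    trends[key] = dose_trend(d, r, direction, alpha, min_doses)
                except ValueError:
                    trends[key] = None
                t = trends[key]
                rec[f"trend_{key}"] = t.rho if t else float("nan")
                rec[f"p_{key}"] = t.p if t else float("nan")
        for name in ("prolif", "diff"):
            mut, ctl = trends.get(f"{name}_mutant"), trends.get(f"{name}_control")
            rec[f"specific_{name}"] = bool(
                mut is not None and mut.significant
                and not (ctl is not None and ctl.significant)
            )
        rec["selected"] = rec["specific_prolif"] and rec["specific_diff"]
        rows.append(rec)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ qPCR


def delta_delta_ct(ct_table: pd.DataFrame, target: str, refs, calibrator: str) -> pd.DataFrame:
    """ΔΔCt relative quantification.

    ΔCt = Ct_target - mean(Ct_refs); ΔΔCt = ΔCt_sample - ΔCt_calibrator;
    fold change = 2^(-ΔΔCt); the relative-to-reference level 2^(-ΔCt) is
    also reported. Samples with a missing Ct are excluded.
    """
    refs = list(refs)
    if not refs:
        raise ConfigError("need at least one reference gene")
    wide = ct_table.pivot_table(index="sample", columns="gene", values="ct")
    needed = [target] + refs
    missing = [g for g in needed if g not in wide.columns]
    if missing:
        raise ConfigError(f"genes missing from Ct table: {missing}")
    ok = wide[needed].dropna()
    dct = ok[target] - ok[refs].mean(axis=1)
    if calibrator not in dct.index:
        raise ConfigError(f"calibrator sample {calibrator!r} not present/complete")
    ddct = dct - dct.loc[calibrator]
    return pd.DataFrame({
        "sample": dct.index,
        "delta_ct": dct.to_numpy(),
        "delta_delta_ct": ddct.to_numpy(),
        "fold_change": np.power(2.0, -ddct.to_numpy()),
        "rel_to_reference": np.power(2.0, -dct.to_numpy()),
        "excluded": False,
    }).reset_index(drop=True)


# ----------------------------------------------------------- Welch's t-test


def welch_t(group_a, group_b) -> dict:
    """Welch's unequal-variances t-test with Welch–Satterthwaite df
    (two-sided p)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    se = np.sqrt(va + vb)
    if se == 0:
        return {"t": 0.0, "df": float(a.size + b.size - 2), "p": 1.0}
    t = (a.mean() - b.mean()) / se
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


# ------------------------------------------------------- model / results


class ScreenModel:
    """Statsmodels-style front end for the screening analysis.

    Built from a long well table; ``fit()`` runs normalization, plate QC,
    hit calling and replicate concordance and returns a
    :class:`ScreenResults`.
    """

    def __init__(self, table: pd.DataFrame, k: float = 3.0,
                 toxicity_cutoff: float = 2000, z_min: float = 0.2,
                 min_dmso_wells: int = 8, mode: str = "centered",
                 sd_scope: str = "global"):
        required = {"plate", "well", "compound", "role", "replicate",
                    "ki67_ratio", "hucd_ratio", "nuclei_count"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigError(f"well table missing columns: {sorted(missing)}")
        self.table = table
        self.k = k
        self.toxicity_cutoff = toxicity_cutoff
        self.z_min = z_min
        self.min_dmso_wells = min_dmso_wells
        self.mode = mode
        self.sd_scope = sd_scope

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "ScreenModel":
        return cls(table, **kwargs)

    def fit(self) -> "ScreenResults":
        norm = median_normalize(self.table, self.mode, self.min_dmso_wells)
        norm = plate_qc(norm, self.z_min)
        hitcall = call_hits(norm, self.k, self.toxicity_cutoff, self.sd_scope)
        conc = replicate_concordance(norm)
        return ScreenResults(self, norm, hitcall, conc)


class ScreenResults:
    """Fitted screen: normalized table, QC record, hit calls, concordance."""

    def __init__(self, model: ScreenModel, normalized: NormalizedScreen,
                 hitcall: HitCallResult, concordance: dict):
        self.model = model
        self.normalized = normalized
        self.hitcall = hitcall
        self.concordance = concordance

    @property
    def hits(self) -> list:
        return self.hitcall.hits

    @property
    def n_hits(self) -> int:
        return self.hitcall.n_hits

    def mean_z_prime(self, metric: str = "ki67") -> float:
        qc = self.normalized.qc
        return float(qc["z_prime_" + metric].mean())

    def plot_quadrant(self, ax=None):
        """Hit-calling scatter: normalized HuC/D vs Ki67 per compound, with
        the 3-SD window and hits/toxics highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        df = self.hitcall.per_compound
        th = self.hitcall.thresholds
        rest = df[~df["hit"] & ~df["toxic"]]
        ax.scatter(df["ki67_norm"], df["hucd_norm"], s=4, c="0.7", label="compound")
        ax.scatter(rest.loc[rest["in_window"], "ki67_norm"],
                   rest.loc[rest["in_window"], "hucd_norm"], s=8, c="0.4")
        ax.scatter(df.loc[df["toxic"], "ki67_norm"], df.loc[df["toxic"], "hucd_norm"],
                   s=8, c="k", marker="x", label="toxic")
        ax.scatter(df.loc[df["hit"], "ki67_norm"], df.loc[df["hit"], "hucd_norm"],
                   s=10, c="tab:red", label="hit")
        ax.axvline(th["median_ki67"] + th["k"] * th["sd_ki67"], ls="--", lw=0.8, c="k")
        ax.axhline(th["median_hucd"] - th["k"] * th["sd_hucd"], ls="--", lw=0.8, c="k")
        ax.set_xlabel("normalized Ki67 ratio")
        ax.set_ylabel("normalized HuC/D ratio")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def summary(self) -> str:
        qc = self.normalized.qc
        th = self.hitcall.thresholds
        lines = [
            "Screen hit-calling summary",
            "==========================",
            f"wells: {len(self.normalized.table):>8d}   plates: {qc.shape[0]}"
            f" (passing: {int(qc['pass'].sum())}, excluded pre-QC:"
            f" {len(self.normalized.excluded_plates)})",
            f"mean Z' (Ki67):  {self.mean_z_prime('ki67'):7.3f}",
            f"mean Z' (HuC/D): {self.mean_z_prime('hucd'):7.3f}",
            f"replicate r (Ki67):  {self.concordance['pearson_ki67']:6.3f}",
            f"replicate r (HuC/D): {self.concordance['pearson_hucd']:6.3f}",
            f"hit window: > median + {th['k']:g} SD (Ki67) and"
            f" < median - {th['k']:g} SD (HuC/D), {th['sd_scope']} SD",
            f"toxicity: mean nuclei < {th['toxicity_cutoff']:g}",
            f"compounds tested: {len(self.hitcall.per_compound)}",
            f"toxic compounds:  {int(self.hitcall.per_compound['toxic'].sum())}",
            f"hits: {self.n_hits}",
        ]
        return "\n".join(lines)
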
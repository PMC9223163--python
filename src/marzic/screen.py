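"""Table-wide per-taxon mediation screening with FDR control.

Each taxon of a composition table is analyzed as a mediator one at a time:
build the (y, m*, r, L, x) dataset, maximize the zero-inflated likelihood,
and test the abundance (NIE1) and presence (NIE2) components of the
mediation effect with delta-method Wald p-values.  Raw p-values are
adjusted with the Benjamini-Hochberg step-up procedure at a target FDR
(default 20%); the NIE1 and NIE2 families are adjusted separately, since
they are distinct detection tasks.  Taxa that are absent everywhere, have
too few positive observations, or fail to converge are flagged and
excluded from the family size.  Confidence intervals are reported
unadjusted; only the significance flags use the FDR correction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import InteractionSpec, MarzicError, MediationDataset
from .effects import EffectSpec, effects_ci
from .estimation import fit_mle
from .likelihood import QuadratureSpec


def bh_adjust(p: Sequence[float], fdr: float = 0.20
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted_p, reject)``; rejection follows the step-up rule at
    the target FDR and adjusted p-values use the monotone
    cumulative-minimum construction.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    reject, p_adj, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return p_adj, reject


@dataclass
class ScreenResult:
    """Per-taxon effect table with raw/adjusted p-values and flags."""

    table: pd.DataFrame
    fdr: float
    spec: EffectSpec

    def significant(self, effect: str = "nie1") -> pd.DataFrame:
        col = f"{effect}_significant"
        return self.table[self.table[col].fillna(False)]


@dataclass(frozen=True)
class MetricReport:
    """Confusion counts and recall/precision/F1 for one detection task."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        # by convention precision is 1 when there are no false positives
        if self.fp == 0:
            return 1.0
        return self.tp / (self.tp + self.fp)

    @property
    def f1(self) -> float:
        r, p = self.recall, self.precision
        if not np.isfinite(r) or (r + p) == 0:
            return float("nan")
        return 2.0 * r * p / (r + p)


def screen_taxa(
    composition: np.ndarray,
    y: Sequence[float],
    x: Sequence[float],
    lib: Sequence[float],
    spec: EffectSpec = EffectSpec(),
    fdr: float = 0.20,
    taxa: Optional[Sequence[str]] = None,
    min_positive: int = 5,
    quad: QuadratureSpec = QuadratureSpec(),
    interactions: InteractionSpec = InteractionSpec(),
) -> ScreenResult:
    """Fit every taxon as a mediator and flag significant NIE1/NIE2.

    ``composition`` is an n x (K+1) relative-abundance matrix aligned with
    ``y``, ``x`` and ``lib``.  Each fitted taxon contributes one row with
    estimates, standard errors, unadjusted CIs and raw p-values; BH
    adjustment runs separately over the NIE1 and NIE2 p-value families of
    the successfully fitted taxa.
    """
    composition = np.asarray(composition, float)
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    lib = np.asarray(lib, float)
    n, K1 = composition.shape
    if not (len(y) == len(x) == len(lib) == n):
        raise ValueError("composition, y, x, lib must have aligned lengths")
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    if taxa is None:
        taxa = [f"taxon{j+1}" for j in range(K1)]

    rows = []
    for j in range(K1):
        m = composition[:, j]
        row: dict = {"taxon": taxa[j], "n_positive": int((m > 0).sum()),
                     "n_zero": int((m == 0).sum()), "converged": False,
                     "skipped_reason": ""}
        if row["n_positive"] == 0:
            row["skipped_reason"] = "absent in all samples"
            rows.append(row)
            continue
        if row["n_positive"] < min_positive:
            row["skipped_reason"] = (
                f"fewer than {min_positive} positive observations")
            rows.append(row)
            continue
        data = MediationDataset.from_arrays(y, m, lib, x, taxon=taxa[j])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_mle(data, quad=quad, interactions=interactions)
            if not fit.converged:
                row["skipped_reason"] = f"fit did not converge: {fit.message}"
                rows.append(row)
                continue
            est = effects_ci(fit, spec)
        except MarzicError as err:
            row["skipped_reason"] = str(err)
            rows.append(row)
            continue
        row["converged"] = True
        for name in ("nie1", "nie2", "nie", "nde", "cde"):
            e = est[name]
            row[f"{name}_estimate"] = e.estimate
            row[f"{name}_se"] = e.se
            row[f"{name}_ci_low"] = e.ci_low
            row[f"{name}_ci_high"] = e.ci_high
            row[f"{name}_p"] = e.p_value
        rows.append(row)

    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise MarzicError("all taxa were skipped; nothing to screen")

    fitted = table["converged"].to_numpy()
    for name in ("nie1", "nie2"):
        adj = np.full(K1, np.nan)
        sig = np.zeros(K1, dtype=object)
        sig[:] = pd.NA
        p_adj, reject = bh_adjust(table.loc[fitted, f"{name}_p"].to_numpy(), fdr)
        adj[fitted] = p_adj
        sig[fitted] = reject
        table[f"{name}_p_adjusted"] = adj
        table[f"{name}_significant"] = pd.array(sig, dtype="boolean")

    return ScreenResult(table=table, fdr=fdr, spec=spec)


def evaluate(results: ScreenResult, truth: pd.DataFrame
             ) -> dict[str, MetricReport]:
    """Confusion metrics of the significance flags against truth labels.

    ``truth`` must carry ``taxon``, ``nie1_nonzero`` and ``nie2_nonzero``
    columns aligned by taxon name.  Skipped taxa count as non-detections.
    """
    merged = results.table.merge(truth, on="taxon", how="left", validate="1:1")
    if merged["nie1_nonzero"].isna().any():
        raise ValueError("truth labels do not cover every screened taxon")
    out = {}
    for name in ("nie1", "nie2"):
        called = merged[f"{name}_significant"].fillna(False).to_numpy(bool)
        true_pos = merged[f"{name}_nonzero"].to_numpy(bool)
        out[name] = MetricReport(
            tp=int((called & true_pos).sum()),
            fp=int((called & ~true_pos).sum()),
            tn=int((~called & ~true_pos).sum()),
            fn=int((~called & true_pos).sum()),
        )
    return out


def heatmap_table(results: ScreenResult,
                  composition: Optional[np.ndarray] = None,
                  samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Signed mediation-strength values for heatmap rendering.

    Strength per taxon is ``(1 - raw NIE1 p-value)`` carrying the sign of
    the NIE1 estimate.  Without a composition matrix, returns one row per
    taxon; with one, returns a taxa x samples matrix where entries for
    samples lacking the taxon are left missing.
    """
    tab = results.table
    strength = np.sign(tab.get("nie1_estimate", pd.Series(np.nan, index=tab.index)))
    strength = strength * (1.0 - tab.get("nie1_p", pd.Series(np.nan, index=tab.index)))
    per_taxon = pd.DataFrame({"taxon": tab["taxon"], "strength": strength})
    if composition is None:
        return per_taxon
    composition = np.asarray(composition, float)
    n = composition.shape[0]
    if samples is None:
        samples = [f"sample{i+1}" for i in range(n)]
    mat = np.repeat(per_taxon["strength"].to_numpy()[:, None], n, axis=1)
    mat = np.where(composition.T > 0, mat, np.nan)
    return pd.DataFrame(mat, index=per_taxon["taxon"], columns=samples)


# ---------------------------------------------------------------------------
# Tabular input/output
# ---------------------------------------------------------------------------

def read_feature_table(path, orientation: str = "samples_by_taxa"
                       ) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature-table TSV; returns (composition, taxa, samples).

    ``orientation`` states what the file's rows are; the returned matrix is
    always samples x taxa.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_by_samples":
        df = df.T
    elif orientation != "samples_by_taxa":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df.to_numpy(float), [str(c) for c in df.columns], [str(i) for i in df.index]


def read_metadata(path, outcome_col: str = "outcome",
                  exposure_col: str = "exposure",
                  lib_size_col: str = "lib_size",
                  sample_col: str = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {outcome_col, exposure_col, lib_size_col, sample_col} - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return df.rename(columns={outcome_col: "outcome", exposure_col: "exposure",
                              lib_size_col: "lib_size", sample_col: "sample_id"})


def write_results(path, results: ScreenResult) -> None:
    results.table.to_csv(path, sep="\t", index=False)


def write_manifest(path, config: dict) -> None:
    import marzic

    manifest = {"package": "marzic", "version": marzic.__version__}
    manifest.update(config)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


__all__ = [
    "bh_adjust", "ScreenResult", "MetricReport", "screen_taxa", "evaluate",
    "heatmap_table", "read_feature_table", "read_metadata",
    "write_results", "write_manifest",
]
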
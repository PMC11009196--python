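"""End-to-end orchestration: deficits -> FIs -> models -> AUC tests -> FDR.

`run_panel` executes, for every biomarker in a panel, the four-model fit on
the common sample, the four pairwise AUC-equality contrasts, and the BH
screen across the panel, and assembles a publication-style summary table
(one row per biomarker, one significance flag per contrast, plus a totals
row counting improvements per contrast).

The four contrasts, in reporting order:

* ``M2_vs_M1`` - does the biomarker improve the age-sex model?
* ``M3_vs_M1`` - does the leave-one-out FI improve the age-sex model?
* ``M4_vs_M2`` - does the FI add to the age-sex-biomarker model?
* ``M4_vs_M3`` - does the biomarker add to the age-sex-FI model?
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coding import code_matrix
from .config import SimulationConfig
from .dictionary import DataDictionary
from .errors import DegenerateSampleError, FrailtyKitError
from .frailty import compute_fi_vector
from .models import fit_model_family
from .roc import auc_weighted, test_auc_equality
from .screening import DEFAULT_FDR, screen_family

logger = logging.getLogger("frailtykit")

CONTRASTS = (("M2_vs_M1", "M2", "M1"),
             ("M3_vs_M1", "M3", "M1"),
             ("M4_vs_M2", "M4", "M2"),
             ("M4_vs_M3", "M4", "M3"))
CONTRAST_LABELS = tuple(c[0] for c in CONTRASTS)

__all__ = ["PanelResult", "run_panel", "describe_cohort", "render_summary",
           "build_manifest", "plot_auc_dots", "CONTRAST_LABELS"]


@dataclass
class PanelResult:
    """Everything `run_panel` produces for one panel."""

    panel: str
    summary: pd.DataFrame       # one row per biomarker
    comparisons: pd.DataFrame   # one row per biomarker x contrast
    totals: pd.Series           # improved-flag counts per contrast
    skipped: List[str] = field(default_factory=list)

    def summary_with_totals(self) -> pd.DataFrame:
        total_row = {"biomarker": "Total", "panel": self.panel, "domain": ""}
        for label in CONTRAST_LABELS:
            total_row[f"improved_{label}"] = int(self.totals[label])
        return pd.concat(
            [self.summary, pd.DataFrame([total_row])], ignore_index=True
        )


def run_panel(cohort: pd.DataFrame, dictionary: DataDictionary, panel: str,
              q: float = DEFAULT_FDR, family_mode: str = "contrast"
              ) -> PanelResult:
    """Run the full comparison chain for every biomarker of one panel.

    A biomarker whose common sample is degenerate (empty, or single outcome
    class) is reported in ``skipped`` rather than aborting the panel.
    """
    panel_dict = dictionary.panel(panel)
    deficit_matrix = code_matrix(cohort, panel_dict)
    rows: List[dict] = []
    comp_rows: List[dict] = []
    skipped: List[str] = []
    for rule in panel_dict:
        name = rule.item_name
        try:
            fitted = fit_model_family(cohort, dictionary, name,
                                      deficit_matrix=deficit_matrix)
        except DegenerateSampleError as exc:
            logger.warning("skipping %s: %s", name, exc)
            skipped.append(name)
            continue
        mask_index = fitted["M1"].index
        sub = cohort.loc[mask_index]
        y = sub["died"].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        aucs = {mid: auc_weighted(fm.predicted_risk, y, w)
                for mid, fm in fitted.items()}
        row = {"biomarker": name, "panel": panel, "domain": rule.domain,
               "n_used": fitted["M1"].n_used}
        for mid, res in aucs.items():
            row[f"auc_{mid}"] = res.auc
            row[f"ci_low_{mid}"], row[f"ci_high_{mid}"] = res.ci95
        rows.append(row)
        for label, hi, lo in CONTRASTS:
            cmp_res = test_auc_equality(
                fitted[hi].predicted_risk, fitted[lo].predicted_risk, y, w,
                label_a=hi, label_b=lo)
            comp_rows.append({
                "biomarker": name, "panel": panel, "contrast": label,
                "auc_a": cmp_res.auc_a, "auc_b": cmp_res.auc_b,
                "chi2": cmp_res.chi2, "p_value": cmp_res.p_value,
            })
        logger.info("%s: n=%d, converged=%s", name, fitted["M1"].n_used,
                    all(fm.converged for fm in fitted.values()))
    if not rows:
        raise FrailtyKitError(f"no usable biomarker in panel {panel!r}")
    summary = pd.DataFrame(rows)
    comparisons = screen_family(pd.DataFrame(comp_rows), q=q,
                                family_mode=family_mode)
    flag_map = comparisons.pivot(index="biomarker", columns="contrast",
                                 values="rejected")
    for label in CONTRAST_LABELS:
        summary[f"improved_{label}"] = (
            summary["biomarker"].map(flag_map[label]).astype(bool)
        )
    totals = pd.Series(
        {label: int(summary[f"improved_{label}"].sum())
         for label in CONTRAST_LABELS},
        name="total_improved",
    )
    return PanelResult(panel=panel, summary=summary, comparisons=comparisons,
                       totals=totals, skipped=skipped)


def _weighted_mean_sd(x: pd.Series, w: pd.Series) -> Tuple[float, float]:
    ok = x.notna()
    xv = x[ok].to_numpy(dtype=float)
    wv = w[ok].to_numpy(dtype=float)
    if len(xv) == 0:
        return np.nan, np.nan
    mean = np.average(xv, weights=wv)
    var = np.average((xv - mean) ** 2, weights=wv)
    return float(mean), float(np.sqrt(var))


def describe_cohort(cohort: pd.DataFrame,
                    fi_blood: Optional[pd.DataFrame] = None,
                    fi_exam: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Weighted baseline characteristics, overall and by mortality status.

    Rows: counts, weighted mean (SD) of age and the two FIs, weighted %
    female. Columns: overall / survived / died; a stratum with no
    participants yields NaN entries rather than an error.
    """
    strata = {
        "overall": cohort.index,
        "survived": cohort.index[cohort["died"] == 0],
        "died": cohort.index[cohort["died"] == 1],
    }
    out: Dict[str, dict] = {}
    for name, idx in strata.items():
        sub = cohort.loc[idx]
        w = sub["weight"]
        col = {"n": int(len(sub))}
        if len(sub):
            col["age_mean"], col["age_sd"] = _weighted_mean_sd(sub["age"], w)
            female = (sub["sex"] == "female").astype(float)
            col["pct_female"] = float(np.average(female, weights=w) * 100.0)
        else:
            col["age_mean"] = col["age_sd"] = col["pct_female"] = np.nan
        for label, fi in (("fi_blood", fi_blood), ("fi_exam", fi_exam)):
            if fi is not None and len(sub):
                m, s = _weighted_mean_sd(fi.loc[idx, "value"], w)
                col[f"{label}_mean"], col[f"{label}_sd"] = m, s
            elif fi is not None:
                col[f"{label}_mean"] = col[f"{label}_sd"] = np.nan
        out[name] = col
    return pd.DataFrame(out)


def render_summary(summary: pd.DataFrame, totals: Optional[pd.Series] = None,
                   check: str = "✓", dash: str = "–") -> str:
    """Format a panel summary as a fixed-width text table with check marks."""
    headers = ["Biomarker", "Domain", "n"] + list(CONTRAST_LABELS)
    lines = []
    body: List[List[str]] = []
    for _, row in summary.iterrows():
        cells = [str(row["biomarker"]), str(row.get("domain", "")),
                 str(row.get("n_used", ""))]
        for label in CONTRAST_LABELS:
            flag = row.get(f"improved_{label}", False)
            cells.append(check if bool(flag) else dash)
        body.append(cells)
    if totals is None and len(summary):
        totals = pd.Series({label: int(summary[f"improved_{label}"].sum())
                            for label in CONTRAST_LABELS})
    if totals is not None:
        body.append(["Total", "", ""] +
                    [str(int(totals[label])) for label in CONTRAST_LABELS])
    widths = [max(len(h), *(len(r[i]) for r in body)) if body else len(h)
              for i, h in enumerate(headers)]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines.append(fmt.format(*headers))
    lines.append("  ".join("-" * w for w in widths))
    for cells in body:
        lines.append(fmt.format(*cells))
    return "\n".join(lines)


def build_manifest(files: Dict[str, str],
                   config: Optional[SimulationConfig] = None,
                   dictionary: Optional[DataDictionary] = None,
                   row_counts: Optional[Dict[str, int]] = None,
                   seed: Optional[int] = None) -> dict:
    """Reproducibility manifest: content hashes of every emitted artifact."""
    from . import __version__

    def _sha256(path: str) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    manifest = {
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "files": {label: {"path": path, "sha256": _sha256(path)}
                  for label, path in files.items()},
        "row_counts": row_counts or {},
    }
    if config is not None:
        cfg = json.dumps(config.to_dict(), sort_keys=True)
        manifest["config"] = config.to_dict()
        manifest["config_sha256"] = hashlib.sha256(cfg.encode()).hexdigest()
    if dictionary is not None:
        dic = json.dumps(dictionary.to_records(), sort_keys=True)
        manifest["dictionary_sha256"] = hashlib.sha256(dic.encode()).hexdigest()
    return manifest


def plot_auc_dots(summary: pd.DataFrame, path: str,
                  model_id: str = "M2") -> None:
    """Convenience dot-and-CI plot of per-biomarker AUCs (unstyled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.25 * len(summary) + 1.5))
    y = np.arange(len(summary))
    auc = summary[f"auc_{model_id}"]
    lo = summary[f"ci_low_{model_id}"]
    hi = summary[f"ci_high_{model_id}"]
    ax.errorbar(auc, y, xerr=[auc - lo, hi - auc], fmt="o", markersize=3,
                capsize=2)
    ax.set_yticks(y)
    ax.set_yticklabels(summary["biomarker"], fontsize=6)
    ax.set_xlabel(f"AUC ({model_id}) with 95% CI")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
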
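"""FDG-PET quantification: region mean counts, SUV, SUVR, treatment % change,
and agreement statistics between VOI-definition methods.

SUV(t) = C_PET(t) / (ID / BW) with the small-animal convention of unit tissue
density (1 g = 1 mL), so ID/BW in kBq/g is an activity concentration and SUV
is dimensionless.  SUVR divides the target region's SUV by the cerebellar
reference SUV; the ID/BW factor cancels, so SUVR equals the plain ratio of
region mean counts.  Three VOI-definition routes are compared: ``DL``
(network-predicted VOIs on native PET), ``iGT`` (inverse-normalized template
VOIs on native PET — the training labels), and ``GT`` (the template VOI on
spatially normalized, i.e. template-space, PET).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask, ImageVolume, LabelVolume, REGION_NAMES
from .metrics import ccc

DL, IGT, GT = "DL", "iGT", "GT"
REFERENCE_REGION = "cerebellum"


@dataclass(frozen=True)
class QuantRecord:
    mouse_id: str
    session: str
    method: str  # DL | iGT | GT
    region: str
    mean_count: float  # activity concentration, kBq/mL
    suv: float
    suvr: float


def _region_mask(region, code: int | None = None) -> np.ndarray:
    if isinstance(region, BinaryMask):
        return region.data
    if isinstance(region, LabelVolume):
        if code is None:
            raise ValueError("a region code is required with a label volume")
        return region.data == code
    return np.asarray(region).astype(bool)


def mean_count(pet: ImageVolume, region, code: int | None = None) -> float:
    """Arithmetic mean of PET voxel values inside a region."""
    m = _region_mask(region, code)
    if m.shape != pet.shape:
        raise ValueError(f"region shape {m.shape} does not match PET grid {pet.shape}")
    if not m.any():
        name = REGION_NAMES.get(code, code) if code is not None else "mask"
        raise ValueError(f"empty region ({name}): mean count undefined")
    return float(pet.data[m].mean())


def suv(mean_count_kbq_ml: float, injected_dose_kbq: float, body_weight_g: float) -> float:
    """Standardized uptake value, C / (ID / BW), density 1 g/mL."""
    if injected_dose_kbq <= 0 or body_weight_g <= 0:
        raise ValueError("injected dose and body weight must be positive")
    return float(mean_count_kbq_ml / (injected_dose_kbq / body_weight_g))


def suvr(
    pet: ImageVolume,
    labels: LabelVolume,
    target_code: int,
    reference_code: int | None = None,
) -> float:
    """SUV ratio of a target region to the (cerebellar) reference region."""
    from .core import CEREBELLUM

    if reference_code is None:
        reference_code = CEREBELLUM
    ref = mean_count(pet, labels, reference_code)
    if ref <= 0:
        raise ValueError("reference region mean must be positive")
    return mean_count(pet, labels, target_code) / ref


def pct_change(suvr_bl: float, suvr_fu: float) -> float:
    """Baseline -> follow-up percentage change, 100 * (FU - BL) / BL."""
    if suvr_bl <= 0:
        raise ValueError("baseline SUVR must be positive")
    return 100.0 * (suvr_fu - suvr_bl) / suvr_bl


def quantify(
    pet: ImageVolume,
    labels: LabelVolume,
    injected_dose_kbq: float,
    body_weight_g: float,
    mouse_id: str,
    session: str,
    method: str,
) -> list[QuantRecord]:
    """Per-region mean count, SUV, and SUVR for one scan under one VOI route."""
    from .core import CEREBELLUM

    ref_count = mean_count(pet, labels, CEREBELLUM)
    out = []
    for code, region in REGION_NAMES.items():
        c = mean_count(pet, labels, code)
        out.append(
            QuantRecord(
                mouse_id=mouse_id,
                session=session,
                method=method,
                region=region,
                mean_count=c,
                suv=suv(c, injected_dose_kbq, body_weight_g),
                suvr=c / ref_count,
            )
        )
    return out


def records_frame(records: list[QuantRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def pct_change_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per (mouse, method, region) SUVR % change from the BL and FU sessions."""
    wide = df.pivot_table(
        index=["mouse_id", "method", "region"], columns="session", values="suvr"
    )
    missing = wide[wide.isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"missing BL/FU sessions for: {sorted(set(missing.index))[:5]}")
    out = wide.reset_index()
    out["pct_change"] = 100.0 * (out["FU"] - out["BL"]) / out["BL"]
    return out[["mouse_id", "method", "region", "pct_change"]]


@dataclass
class MethodComparison:
    """Agreement and treatment-effect statistics between VOI routes."""

    agreement: pd.DataFrame  # per region x method pair: CCC and Pearson r
    pct_changes: pd.DataFrame  # per mouse x method x region
    effect_tests: pd.DataFrame  # per region x method pair: paired & Welch t on % changes

    def to_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.agreement.to_csv(outdir / "method_agreement.csv", index=False)
        self.pct_changes.to_csv(outdir / "suvr_pct_changes.csv", index=False)
        self.effect_tests.to_csv(outdir / "effect_tests.csv", index=False)
        summary = {
            "regions": sorted(self.agreement["region"].unique().tolist()),
            "method_pairs": sorted(self.agreement["pair"].unique().tolist()),
        }
        import json

        (outdir / "comparison_summary.json").write_text(json.dumps(summary, indent=2))


def compare_methods(records: list[QuantRecord] | pd.DataFrame) -> MethodComparison:
    """Three-way method comparison: CCC / Pearson r of counts and SUVRs, and
    paired plus unpaired (Welch) two-sample t-tests on SUVR % changes.

    All methods must cover the same (mouse, session, region) keys; mice seen
    by only a subset of methods are compared on the intersection per pair.
    Degenerate tests (zero-variance differences) are reported as NaN.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    methods = sorted(df["method"].unique())
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    regions = sorted(df["region"].unique())

    def _safe_ccc(x, y):
        try:
            return ccc(x, y)
        except ValueError:
            return np.nan

    def _safe_r(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(stats.pearsonr(x, y)[0])

    key = ["mouse_id", "session", "region"]
    per_method = {m: df[df["method"] == m].set_index(key) for m in methods}
    agreement_rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            common = per_method[m1].index.intersection(per_method[m2].index)
            if len(common) == 0:
                raise ValueError(f"no matched (mouse, session, region) keys for {m1} vs {m2}")
            a = per_method[m1].loc[common]
            b = per_method[m2].loc[common]
            for region in regions:
                sel = common.get_level_values("region") == region
                if sel.sum() < 2:
                    continue
                x_cnt, y_cnt = a.loc[sel, "mean_count"], b.loc[sel, "mean_count"]
                row = {
                    "region": region,
                    "pair": f"{m1}-{m2}",
                    "n": int(sel.sum()),
                    "ccc_count": _safe_ccc(x_cnt, y_cnt),
                    "r_count": _safe_r(x_cnt, y_cnt),
                }
                if region != REFERENCE_REGION:  # SUVR of the reference is 1 by identity
                    x_s, y_s = a.loc[sel, "suvr"], b.loc[sel, "suvr"]
                    row["ccc_suvr"] = _safe_ccc(x_s, y_s)
                    row["r_suvr"] = _safe_r(x_s, y_s)
                else:
                    row["ccc_suvr"] = np.nan
                    row["r_suvr"] = np.nan
                agreement_rows.append(row)

    pct = pct_change_table(df)
    test_rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            for region in regions:
                if region == REFERENCE_REGION:
                    continue
                p1 = pct[(pct["method"] == m1) & (pct["region"] == region)].set_index("mouse_id")
                p2 = pct[(pct["method"] == m2) & (pct["region"] == region)].set_index("mouse_id")
                common = p1.index.intersection(p2.index)
                x = p1.loc[common, "pct_change"].to_numpy()
                y = p2.loc[common, "pct_change"].to_numpy()
                if len(common) < 2:
                    continue
                diffs = x - y
                if np.allclose(diffs.std(ddof=1), 0.0):
                    t_p, p_p = (0.0, 1.0) if np.allclose(diffs, 0.0) else (np.nan, np.nan)
                else:
                    t_p, p_p = stats.ttest_rel(x, y)
                # the unpaired comparison uses each method's full sample
                xu = p1["pct_change"].to_numpy()
                yu = p2["pct_change"].to_numpy()
                if np.allclose(xu.std(ddof=1), 0) and np.allclose(yu.std(ddof=1), 0):
                    t_w, p_w = np.nan, np.nan
                else:
                    t_w, p_w = stats.ttest_ind(xu, yu, equal_var=False)
                test_rows.append(
                    {
                        "region": region,
                        "pair": f"{m1}-{m2}",
                        "n": len(common),
                        "t_paired": float(t_p),
                        "p_paired": float(p_p),
                        "t_welch": float(t_w),
                        "p_welch": float(p_w),
                    }
                )
    return MethodComparison(
        agreement=pd.DataFrame(agreement_rows),
        pct_changes=pct,
        effect_tests=pd.DataFrame(test_rows),
    )
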
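"""Observer-agreement statistics for Cobb-angle measurements.

The package ships a transcription of the reference measurement table:
35 AP radiographs, each measured twice (sessions t=1, t=2) by an expert
and a novice orthopaedist, plus the automatic minimum-bounding-rectangle
(MBR) measurement.  Angles are signed (negative = curve bends
rightward); records the observers graded "no scoliosis" carry angle 0.

The agreement battery mirrors standard inter-observer methodology:
descriptive statistics (mean, population SD, range), one-way ANOVA
across the three measurement sources, pairwise Pearson correlation,
Spearman rank-order correlation via the classical rank-difference
formula

    rho = 1 - 6 * sum d_i^2 / (n (n^2 - 1)),

and the intraclass correlation coefficient, by default the two-way
random-effects, absolute-agreement, single-measure form ICC(2,1).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MeasurementRecord", "load_table", "angle_columns", "descriptive",
    "pearson", "spearman", "one_way_anova", "icc", "classify_rating",
    "agreement_report", "TABLE_SHA256",
]

_TABLE_FILE = "table4_cobb.csv"
#: checksum of the packaged measurement table; load_table refuses silently
#: corrupted fixtures.
TABLE_SHA256 = "d8075f0b90fe4f466e5fc32de1f8d11af57e01277b35a3da9f6e33a3b84ace76"


@dataclass(frozen=True)
class MeasurementRecord:
    image_id: int
    observer: str  # expert | novice | mbr
    session: int | None  # 1 | 2 | None for mbr
    upper_vertebra: str | None
    lower_vertebra: str | None
    cobb_deg: float
    no_scoliosis: bool


def _fixture_bytes() -> bytes:
    return resources.files("spinecurve.data").joinpath(_TABLE_FILE).read_bytes()


def load_table(verify: bool = True) -> pd.DataFrame:
    """The packaged 35-image measurement table as a DataFrame.

    Columns: image, expert/novice upper & lower end-vertebra labels and
    angles per session, MBR labels and angle.  Missing angle cells
    ("no scoliosis") are zero-filled with companion ``*_nos`` flags.
    """
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE_SHA256:
            raise RuntimeError(
                f"measurement table checksum mismatch ({digest[:12]}...); "
                "the packaged fixture is corrupted"
            )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    label_col = {"expert_t1": "expert_upper_t1", "expert_t2": "expert_upper_t2",
                 "novice_t1": "novice_upper_t1", "novice_t2": "novice_upper_t2",
                 "mbr": "mbr_upper"}
    for col, lab in label_col.items():
        # "no scoliosis" cells: angle missing, or zero with no end-vertebra label
        df[col + "_nos"] = df[col].isna() | (df[lab].isna() & (df[col].fillna(0) == 0))
        df[col] = df[col].fillna(0.0)
    return df


def records(df: pd.DataFrame | None = None) -> list[MeasurementRecord]:
    """Long-form view of the measurement table."""
    df = load_table() if df is None else df
    out = []
    for _, row in df.iterrows():
        for obs, sess in (("expert", 1), ("expert", 2), ("novice", 1), ("novice", 2)):
            col = f"{obs}_t{sess}"
            out.append(MeasurementRecord(
                int(row["image"]), obs, sess,
                row.get(f"{obs}_upper_t{sess}") if pd.notna(row.get(f"{obs}_upper_t{sess}")) else None,
                row.get(f"{obs}_lower_t{sess}") if pd.notna(row.get(f"{obs}_lower_t{sess}")) else None,
                float(row[col]), bool(row[f"{col}_nos"]),
            ))
        out.append(MeasurementRecord(
            int(row["image"]), "mbr", None,
            row.get("mbr_upper"), row.get("mbr_lower"),
            float(row["mbr"]), bool(row["mbr_nos"]),
        ))
    return out


def angle_columns(df: pd.DataFrame | None = None, session: int = 1):
    """(expert, novice, mbr) angle vectors for one manual session."""
    df = load_table() if df is None else df
    if session not in (1, 2):
        raise ValueError("session must be 1 or 2")
    return (df[f"expert_t{session}"].to_numpy(float),
            df[f"novice_t{session}"].to_numpy(float),
            df["mbr"].to_numpy(float))


def descriptive(values: Sequence[float]) -> dict:
    """Mean, population SD (n denominator), min and max."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two values")
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=0)),
            "min": float(v.min()), "max": float(v.max()), "n": int(len(v))}


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho via the rank-difference formula on average ranks.

    With ties present the classical 6*sum(d^2) formula is only an
    approximation of Pearson-on-ranks; both agree exactly on tie-free
    data.  The p-value comes from the exact Pearson-of-ranks form.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = 1.0 - 6.0 * float(np.sum((rx - ry) ** 2)) / (n * (n**2 - 1))
    p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def icc(ratings: np.ndarray, form: str = "ICC2") -> float:
    """Intraclass correlation of a subjects x raters matrix.

    ``form``: ICC1 (one-way random), ICC2 (two-way random, absolute
    agreement, single measure; the default), or ICC3 (two-way mixed,
    consistency).  Missing cells are not supported.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("ratings must be (>=3 subjects) x (>=2 raters)")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    import pingouin as pg

    n_sub, n_rat = m.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_rat),
        "rater": np.tile(np.arange(n_rat), n_sub),
        "score": m.ravel(),
    })
    table = pg.intraclass_corr(long, targets="subject", raters="rater",
                               ratings="score")
    key = {"ICC1": "ICC1", "ICC2": "ICC2", "ICC3": "ICC3"}.get(form)
    if key is None:
        raise ValueError(f"unknown ICC form {form!r}")
    # pingouin labels rows ICC1/ICC2/ICC3 or ICC(1,1)/(A,1)/(C,1) by version
    labels = list(table["Type"])
    aliases = {"ICC1": ("ICC1", "ICC(1,1)"), "ICC2": ("ICC2", "ICC(A,1)"),
               "ICC3": ("ICC3", "ICC(C,1)")}[key]
    for lab in aliases:
        if lab in labels:
            return float(table.loc[table["Type"] == lab, "ICC"].iloc[0])
    raise RuntimeError(f"ICC form {form} not found in {labels}")


def classify_rating(value: float) -> str:
    """Verbal agreement band for an ICC value.

    poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent <= 1.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


def agreement_report(df: pd.DataFrame | None = None, session: int = 1) -> dict:
    """Full agreement battery for one manual session vs the MBR column."""
    e, nv, m = angle_columns(df, session=session)
    f, p = one_way_anova(e, nv, m)
    pairs = {"expert_novice": (e, nv), "expert_mbr": (e, m), "novice_mbr": (nv, m)}
    out = {
        "session": session,
        "descriptives": {"expert": descriptive(e), "novice": descriptive(nv),
                         "mbr": descriptive(m)},
        "anova": {"F": f, "p": p},
        "pearson": {}, "spearman": {}, "icc": {},
    }
    for name, (a, b) in pairs.items():
        r, rp = pearson(a, b)
        rho, sp_ = spearman(a, b)
        i = icc(np.column_stack([a, b]))
        out["pearson"][name] = {"r": r, "p": rp}
        out["spearman"][name] = {"rho": rho, "p": sp_}
        out["icc"][name] = {"icc": i, "rating": classify_rating(i)}
    return out
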
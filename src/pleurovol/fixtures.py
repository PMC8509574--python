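"""Bundled published cohort data.

The 15-patient unresectable (R2) cohort — sex, affected side, the
intraoperative cause of unresectability, TLC % of predicted, disease
burden (mm), ipsilateral aerated lung volume (cm3) and the volumetric
difference between contralateral and ipsilateral lung (%) — is embedded
verbatim, guarded by a checksum.  Individual data for the 43 resectable
(MCR) patients were never published; group-level statistics for them can
only be exercised on synthetic cohorts (see :mod:`pleurovol.stats`).
"""

from __future__ import annotations

import hashlib
import io

import pandas as pd

__all__ = ["load_table2", "reconstruct_contralateral", "R2_COHORT_CSV"]

R2_COHORT_CSV = """\
id,sex,side,cause_of_R2,tlc_pct,burden_mm,ipsilateral_volume_cm3,diff_pct
1,M,right,DCWI,88,241,1337.17,49.25
2,M,left,DCWI,71,201,989.9,76.68
3,M,right,DCWI,75,99,1512.07,59.01
4,M,right,DCWI,73,58,2130.43,1.88
5,M,right,DCWI,77,35,1584.56,52.92
6,M,left,Aortic adventitia infiltration,86,183,2009.94,33.98
7,M,left,DCWI,93,133,1683.51,28.39
8,M,right,DCWI,72,181,991.43,75.10
9,M,right,DCWI,74,70,1776.78,46.35
10,M,right,Diaphragmatic pillar infiltration,71,134,2964.71,-28.35
11,M,right,DCWI,80,140,1545.46,47.01
12,M,left,DCWI,56,162,711.33,75.26
13,M,right,DCWI,75,89,1471.99,34.46
14,M,left,DCWI,60,123,1321.67,55.41
15,F,right,DCWI,77,34,1782.33,0.74
"""

_CHECKSUM = "cfee15e19b4b98037899391c512645e9ab78ff47d079029b3ffd5e85ab5eb842"


def load_table2() -> pd.DataFrame:
    """The embedded 15-patient R2 cohort, with ``outcome`` set to ``"R2"``.

    Raises
    ------
    RuntimeError
        If the embedded text does not match its checksum (corrupted
        installation).
    """
    digest = hashlib.sha256(R2_COHORT_CSV.encode()).hexdigest()
    if digest != _CHECKSUM:
        raise RuntimeError("embedded R2 cohort fixture failed its checksum")
    df = pd.read_csv(io.StringIO(R2_COHORT_CSV))
    df["outcome"] = "R2"
    return df


def reconstruct_contralateral(record_or_df):
    """Recover contralateral volume and the cm3 difference from the
    published per-patient fields.

    The percent difference is relative to the contralateral lung, so
    ``contralateral = ipsilateral / (1 - diff_pct/100)`` and
    ``diff_cm3 = contralateral - ipsilateral``.  Accepts a single mapping
    (returns a ``(contralateral_cm3, diff_cm3)`` tuple) or a DataFrame
    (returns a copy with ``contralateral_volume_cm3``/``diff_cm3`` columns).
    """
    if isinstance(record_or_df, pd.DataFrame):
        df = record_or_df.copy()
        if (df["diff_pct"] >= 100).any():
            raise ValueError("diff_pct >= 100: contralateral volume undefined")
        contra = df["ipsilateral_volume_cm3"] / (1.0 - df["diff_pct"] / 100.0)
        df["contralateral_volume_cm3"] = contra
        df["diff_cm3"] = contra - df["ipsilateral_volume_cm3"]
        return df
    ipsi = float(record_or_df["ipsilateral_volume_cm3"])
    dpct = float(record_or_df["diff_pct"])
    if dpct >= 100:
        raise ValueError("diff_pct >= 100: contralateral volume undefined")
    contra = ipsi / (1.0 - dpct / 100.0)
    return contra, contra - ipsi
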
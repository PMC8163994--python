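"""Reference tabular inputs bundled with the package.

Two small tables from the chronic-tinnitus tractometry study this package's
statistical design follows:

* the per-subject demographics of the 19 tinnitus participants (age,
  tinnitus laterality, tinnitus duration, Tinnitus Handicap Inventory score,
  etiology, hearing loss), used to parameterize the synthetic cohort
  generator and as a worked example for the summary statistics;
* the reported significant along-tract group differences per bundle and
  metric (minimum uncorrected p, segment index, t value, Cohen's d,
  post-hoc power), used as worked examples for the effect-size conversions.
"""

from __future__ import annotations

import io

import pandas as pd

# Columns: subject, age (years), laterality (B/L/R), tinnitus duration
# (years), THI score (0-100), etiology (W work / AR army rifle / M music),
# hearing loss (dB).
_TINNITUS_SUBJECTS_TSV = """\
subject\tage_y\tlaterality\tduration_y\tthi\torigin\thl_db
T1\t56\tB\t12\t6\tW\t34
T3\t43\tB\t25\t8\tAR\t14
T4\t38\tB\t15\t26\tAR\t20
T5\t59\tB\t25\t22\tAR\t46
T6\t28\tB\t10\t8\tM\t8
T7\t42\tB\t2\t14\tAR\t18
T8\t43\tB\t14\t32\tAR\t18
T10\t42\tB\t18\t24\tM+AR\t25
T11\t51\tL\t10\t44\tAR\t31
T12\t40\tR\t16\t18\tAR\t10
T16\t26\tL\t1\t12\tAR\t25
T17\t60\tB\t17\t12\tAR\t23
T18\t24\tB\t1\t26\tM\t6
T19\t25\tB\t16\t4\tM\t12
T24\t41\tR\t2\t12\tM\t22
T28\t49\tR\t0.5\t12\tAR\t23
T30\t57\tB\t10\t6\tW\t29
T35\t51\tL\t10\t16\tM\t9
T37\t33\tB\t15\t6\tAR\t11
"""

# Control-group summary (individual control rows were not published):
# hearing loss mean 13.2 (sd 3.8) dB, age mean 42.5 (sd 11.9) years.
CONTROL_SUMMARY = {
    "hl_db": {"mean": 13.2, "sd": 3.8},
    "age_y": {"mean": 42.5, "sd": 11.9},
    "n": 19,
}

# Reported significant group differences: one row per (metric, bundle).
# min_p is uncorrected; segment indexes the 100-segment along-tract axis;
# d and power are the published effect size and post-hoc power.
_GROUP_DIFFERENCES_TSV = """\
metric\tbundle\tmin_p\tsegment\tt\td\tpower
AFD\tIFO_right\t6.70e-08\t17\t-6.764\t2.255\t0.980
AFD\tPOPT_left\t8.32e-07\t10\t-5.942\t1.981\t0.907
AFD\tUF_right\t4.95e-09\t62\t-7.632\t2.544\t0.998
AFD\tT_PAR_left\t1.63e-08\t11\t-7.233\t2.411\t0.993
AFD\tAR_right\t4.70e-05\t29\t4.623\t1.541\t0.554
AFD\tAR_left\t0.00037\t22\t-3.930\t1.310\t0.312
peak_amplitude\tATR_right\t4.48e-06\t14\t5.394\t1.798\t0.802
peak_amplitude\tIFO_right\t1.6e-09\t17\t-8.017\t2.672\t0.999
peak_amplitude\tUF_right\t8.02e-08\t57\t-6.705\t2.235\t0.979
peak_amplitude\tT_PAR_left\t2.23e-07\t9\t-6.371\t2.124\t0.958
FA\tAR_right\t1.30e-05\t34\t5.037\t1.679\t0.702
FA\tIFO_right\t1.64e-08\t17\t-7.231\t2.410\t0.994
FA\tOR_left\t3.10e-08\t51\t7.018\t2.339\t0.990
FA\tPOPT_left\t2.22e-06\t10\t-5.622\t1.874\t0.855
FA\tSTR_left\t9.53e-06\t13\t-5.149\t1.716\t0.736
FA\tUF_right\t1.86e-06\t62\t-5.680\t1.893\t0.867
FA\tT_PAR_left\t6.50e-08\t9\t-6.775\t2.258\t0.982
FA\tT_OCC_left\t2.44e-08\t50\t7.099\t2.366\t0.991
"""

GROUP_SIZES = (19, 19)  # (tinnitus, control)

# Full-cohort age / hearing-loss Pearson correlation reported for the study.
REPORTED_AGE_HL_CORRELATION = 0.545


def tinnitus_subjects() -> pd.DataFrame:
    """Per-subject demographics of the 19 tinnitus participants."""
    return pd.read_csv(io.StringIO(_TINNITUS_SUBJECTS_TSV), sep="\t")


def reported_group_differences() -> pd.DataFrame:
    """Published significant along-tract group differences (18 rows)."""
    return pd.read_csv(io.StringIO(_GROUP_DIFFERENCES_TSV), sep="\t")


def demographic_summary() -> pd.DataFrame:
    """Mean/sd summary of the tinnitus group's confounds, one row per variable."""
    df = tinnitus_subjects()
    rows = []
    for col in ("hl_db", "age_y", "duration_y", "thi"):
        rows.append(
            {
                "variable": col,
                "mean": df[col].mean(),
                "sd": df[col].std(ddof=1),
                "min": df[col].min(),
                "max": df[col].max(),
            }
        )
    return pd.DataFrame(rows)
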
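"""Published reference values from the coastal multi-omic survey, and checks that the
package's indices reproduce them.

The packaged TSV holds per-sample depths, feature richness, singleton counts and the
printed coverage/Margalef/evenness values for the four assays (bacterial and archaeal
16S OTU tables, metagenomic and metatranscriptomic pORF-cluster tables). A handful of
abundance counts quoted in the survey's running text are kept here as constants; they
are inputs to simple arithmetic checks (percent reduction, fold-change, richness
ratio).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import numpy as np
import pandas as pd

from .diversity import goods_coverage, margalef_d, richness_correlation

# Counts quoted in the survey's running text.
RHODOBACTERACEAE_DAY_NIGHT = (1528, 1268)  # April 2nd-most-abundant OTU, day -> night
CYANOBACTERIA_JAN_DAY_NIGHT = (17, 258)  # January day -> night sequence counts
ARCHAEAL_VS_BACTERIAL_RICHNESS = (63, 999)  # combined OTUs at depth 4070


def load_survey_tables() -> pd.DataFrame:
    """The packaged per-sample summary table, with printed values kept as strings so
    their printed precision is known."""
    ref = resources.files("omicdiv.data") / "survey_diversity_tables.tsv"
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    for col in ("depth", "richness", "singletons"):
        df[col] = df[col].astype("Int64")
    return df


def _printed_decimals(s: str) -> int:
    return len(s.split(".")[1]) if "." in s else 0


def _matches_printed(computed: float, printed: str) -> bool:
    dec = _printed_decimals(printed)
    return round(computed, dec) == float(printed)


def coverage_checks(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute Good's coverage from every (depth, singletons) pair and compare with
    the printed value at its printed precision."""
    df = load_survey_tables() if df is None else df
    rows = []
    for _, r in df.dropna(subset=["coverage"]).iterrows():
        n, n1 = int(r["depth"]), int(r["singletons"])
        counts = np.concatenate([np.ones(n1, dtype=int), [n - n1]])
        computed = goods_coverage(counts)
        rows.append(
            {
                "assay": r["assay"],
                "sample": r["sample"],
                "printed": r["coverage"],
                "computed": computed,
                "passed": _matches_printed(computed, r["coverage"]),
            }
        )
    return pd.DataFrame(rows)


def margalef_checks(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute Margalef d from every printed (S, N) pair."""
    df = load_survey_tables() if df is None else df
    rows = []
    for _, r in df.dropna(subset=["margalef"]).iterrows():
        computed = margalef_d(int(r["richness"]), int(r["depth"]))
        rows.append(
            {
                "assay": r["assay"],
                "sample": r["sample"],
                "printed": r["margalef"],
                "computed": computed,
                "passed": _matches_printed(computed, r["margalef"]),
            }
        )
    return pd.DataFrame(rows)


def transcript_richness_correlation(df: pd.DataFrame | None = None) -> float:
    """Pearson r between 16S OTU richness and resampled metatranscriptomic pORF-cluster
    richness for the seven samples with both assays."""
    df = load_survey_tables() if df is None else df
    bact = df[(df["assay"] == "bacteria_16s") & (df["sample"] != "combined")]
    meta = df[(df["assay"] == "metatranscriptome_porf") & (df["sample"] != "combined")]
    merged = bact.merge(meta, on="sample", suffixes=("_16s", "_mt"))
    return richness_correlation(
        merged["richness_16s"].astype(int), merged["richness_mt"].astype(int)
    )


def text_arithmetic() -> Dict[str, float]:
    """Arithmetic on counts quoted in the survey text: the day-to-night percent
    reduction of the Rhodobacteraceae OTU, the cyanobacterial January fold-change, and
    the archaeal share of bacterial richness."""
    day, night = RHODOBACTERACEAE_DAY_NIGHT
    cy_day, cy_night = CYANOBACTERIA_JAN_DAY_NIGHT
    arch, bact = ARCHAEAL_VS_BACTERIAL_RICHNESS
    return {
        "rhodobacteraceae_reduction_pct": round((day - night) / day * 100),
        "cyanobacteria_night_fold": round(cy_night / cy_day),
        "archaeal_richness_ratio_pct": round(arch / bact * 100),
    }


def verify_survey_values() -> pd.DataFrame:
    """All fixture checks in one pass/fail table."""
    frames = []
    cov = coverage_checks()
    cov.insert(0, "check", "goods_coverage")
    mar = margalef_checks()
    mar.insert(0, "check", "margalef_d")
    frames += [cov, mar]
    r = transcript_richness_correlation()
    frames.append(
        pd.DataFrame(
            [
                {
                    "check": "richness_correlation",
                    "assay": "bacteria_16s~metatranscriptome_porf",
                    "sample": "7 shared samples",
                    "printed": "0.87",
                    "computed": r,
                    "passed": round(r, 2) == 0.87,
                }
            ]
        )
    )
    arith = text_arithmetic()
    expected = {
        "rhodobacteraceae_reduction_pct": 17,
        "cyanobacteria_night_fold": 15,
        "archaeal_richness_ratio_pct": 6,
    }
    for name, val in arith.items():
        frames.append(
            pd.DataFrame(
                [
                    {
                        "check": name,
                        "assay": "text",
                        "sample": "",
                        "printed": str(expected[name]),
                        "computed": val,
                        "passed": val == expected[name],
                    }
                ]
            )
        )
    return pd.concat(frames, ignore_index=True)
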
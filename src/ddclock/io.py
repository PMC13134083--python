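"""CSV readers and writers for droplet exports, thresholds and cohorts.

Two droplet CSV dialects are accepted, auto-detected from the header:

* long — columns ``well,channel,amplitude``, one row per droplet per
  channel (the shape of instrument exports);
* wide — a ``well`` column plus one column per channel, one row per
  droplet.

Thresholds come from a CSV with one record per CpG
(``cpg,t_total,t_allele,labeled_allele``); the QC rule from a small JSON
file overriding any of the default gate values.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .droplets import ChannelThresholds, DropletWell, MethylationResult
from .poisson import QCRule
from .simulate_droplets import SimulatedWell


def read_droplet_csv(path: str | Path) -> list[DropletWell]:
    """Read wells from a droplet CSV (long or wide dialect)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "well" not in cols:
        raise ValueError(f"{path}: droplet CSV needs a 'well' column")
    well_col = cols["well"]
    wells: list[DropletWell] = []
    if "channel" in cols and "amplitude" in cols:
        for well_id, grp in df.groupby(well_col, sort=False):
            channels = {
                str(ch): sub[cols["amplitude"]].to_numpy(dtype=float)
                for ch, sub in grp.groupby(cols["channel"], sort=False)
            }
            wells.append(DropletWell(well_id=str(well_id), channel_amplitudes=channels))
    else:
        channel_cols = [c for c in df.columns if c != well_col]
        if not channel_cols:
            raise ValueError(f"{path}: wide droplet CSV has no channel columns")
        for well_id, grp in df.groupby(well_col, sort=False):
            channels = {c: grp[c].to_numpy(dtype=float) for c in channel_cols}
            wells.append(DropletWell(well_id=str(well_id), channel_amplitudes=channels))
    return wells


def write_droplet_csv(wells: Iterable[SimulatedWell | DropletWell], path: str | Path) -> None:
    """Write wells in the long dialect (``well,channel,amplitude``)."""
    frames = []
    for item in wells:
        well = item.well if isinstance(item, SimulatedWell) else item
        for cpg, amps in well.channel_amplitudes.items():
            frames.append(
                pd.DataFrame(
                    {"well": well.well_id, "channel": cpg, "amplitude": amps}
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.2f")


def write_truth_csv(wells: Iterable[SimulatedWell], path: str | Path) -> None:
    """Write per-channel ground truth of simulated wells."""
    rows = []
    for sim in wells:
        for cpg, t in sim.truth.items():
            counts = t.cluster_counts()
            rows.append(
                {
                    "well": sim.well.well_id,
                    "channel": cpg,
                    "true_beta": t.true_beta,
                    "labeled_allele": t.labeled_allele,
                    "n_methylated_molecules": t.n_methylated_molecules,
                    "n_unmethylated_molecules": t.n_unmethylated_molecules,
                    "n_negative": counts.n_negative,
                    "n_positive_total": counts.n_positive_total,
                    "n_allele": counts.n_allele,
                    "n_rain": int(t.rain.sum()),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_thresholds_csv(path: str | Path) -> list[ChannelThresholds]:
    """Read per-CpG thresholds (``cpg,t_total,t_allele[,labeled_allele]``)."""
    df = pd.read_csv(path)
    required = {"cpg", "t_total", "t_allele"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: thresholds CSV needs columns {sorted(required)}")
    out = []
    for rec in df.to_dict("records"):
        allele = rec.get("labeled_allele")
        if allele is None or (isinstance(allele, float) and math.isnan(allele)):
            allele = None
        out.append(
            ChannelThresholds(
                cpg=str(rec["cpg"]),
                t_total=float(rec["t_total"]),
                t_allele=float(rec["t_allele"]),
                labeled_allele=allele,
            )
        )
    return out


def write_thresholds_csv(thresholds: Sequence[ChannelThresholds], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cpg": t.cpg,
                "t_total": t.t_total,
                "t_allele": t.t_allele,
                "labeled_allele": t.labeled_allele,
            }
            for t in thresholds
        ]
    ).to_csv(path, index=False)


def read_qc_rule(path: str | Path | None) -> QCRule:
    """Read a QC rule JSON (missing keys fall back to the defaults)."""
    if path is None:
        return QCRule()
    doc = json.loads(Path(path).read_text())
    return QCRule(**doc)


def results_frame(well_id: str, results: Sequence[MethylationResult]) -> pd.DataFrame:
    """Tidy per-CpG quantification table for one well."""
    rows = []
    for r in results:
        counts, qc = r.counts, r.qc
        rows.append(
            {
                "well": well_id,
                "cpg": r.cpg,
                "beta": r.beta,
                "n_methylated": r.n_methylated,
                "n_unmethylated": r.n_unmethylated,
                "n_total": counts.n_total if counts else np.nan,
                "n_positive_total": counts.n_positive_total if counts else np.nan,
                "p_positive": qc.p_positive if qc else np.nan,
                "lambda": qc.lam if qc else np.nan,
                "copies": qc.copies if qc else np.nan,
                "single_fraction": qc.single_fraction if qc else np.nan,
                "qc_pass": qc.passed if qc else False,
                "error": r.error or "",
            }
        )
    return pd.DataFrame(rows)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, validating the age column."""
    df = pd.read_csv(path)
    if "age" not in df.columns:
        raise ValueError(f"{path}: cohort CSV needs an 'age' column")
    return df
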
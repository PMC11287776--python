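"""End-to-end group comparison of an atlas-like multichannel dataset.

Load channels from a manifest, trim padding, screen stationarity, select
age-matched cohorts of five patients per sex per region x state, compute
entropy-complexity curves at tau = 1 and tau = tau_s plus spectral-exponent
fits, and emit a binary difference table per region x state with three
criteria: disjoint k-exponent notches, ellipse separation at tau = 1, and
ellipse separation at tau = tau_s.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ordinal import TimeSeries, ordinal_distribution
from .quantifiers import ec_curve
from .spectral import notch_compare, powerlaw_fit, welch_psd
from .space import ellipse_separation, group_stats
from .timescales import adf_screen, characteristic_time

__all__ = ["ChannelRecord", "PipelineConfig", "CohortSelection",
           "load_channels", "select_cohort", "run_group_analysis",
           "write_report"]

VALID_STATES = {"W", "N2", "N3", "R"}
VALID_SEXES = {"F", "M"}


@dataclass
class ChannelRecord:
    """One labeled channel: signal plus patient/region/state metadata."""

    signal: TimeSeries
    patient_id: str
    sex: str
    hemisphere: str
    region: str
    state: str
    age: float
    channel: str

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r} (expect W/N2/N3/R)")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"unknown sex {self.sex!r} (expect F/M)")
        if not self.region:
            raise ValueError("region must be non-empty")


def _clean_signal(values: np.ndarray) -> tuple:
    """Drop undefined entries and trailing zero-padding; report what was cut."""
    x = np.asarray(values, float)
    n_nan = int(np.isnan(x).sum())
    x = x[~np.isnan(x)]
    n0 = x.size
    x = np.trim_zeros(x, trim="b")
    return x, {"nan_removed": n_nan, "padding_trimmed": int(n0 - x.size)}


def _read_signal(path: Path, column: str | None, fmt: str | None = None):
    """Load one signal from a CSV/TSV column or an EDF channel."""
    suffix = (fmt or path.suffix.lstrip(".")).lower()
    if suffix == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if column and column in raw.ch_names:
            data = raw.get_data(picks=[column])[0]
        elif column:
            raise KeyError(f"EDF channel {column!r} not in {raw.ch_names}")
        else:
            data = raw.get_data()[0]
        return np.asarray(data, float), float(raw.info["sfreq"])
    sep = "\t" if suffix in ("tsv", "tab") else ","
    df = pd.read_csv(path, sep=sep)
    if column:
        if column not in df.columns:
            raise KeyError(f"column {column!r} not in {path.name}")
        col = df[column]
    else:
        col = df.iloc[:, 0]
    return col.to_numpy(dtype=float), None


def load_channels(manifest_path: str | Path):
    """Load ChannelRecords from a manifest table.

    The manifest (TSV/CSV) must carry columns file, patient_id, sex,
    hemisphere, region, state, age, channel, sampling_rate and optionally
    column (CSV column name or EDF channel).  Signals are cleaned of NaNs
    and trailing zero-padding.  Returns ``(records, report)`` where report
    lists per-row rejections and cleaning actions.
    """
    manifest_path = Path(manifest_path)
    sep = "\t" if manifest_path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(manifest_path, sep=sep)
    base = manifest_path.parent
    records, report = [], []
    for i, row in table.iterrows():
        try:
            src = base / str(row["file"])
            column = str(row["column"]) if "column" in table.columns and pd.notna(row.get("column")) else None
            values, sfreq = _read_signal(src, column)
            cleaned, actions = _clean_signal(values)
            if cleaned.size < 2:
                raise ValueError("signal empty after cleaning")
            rate = float(row["sampling_rate"]) if pd.notna(row.get("sampling_rate")) else sfreq
            rec = ChannelRecord(
                signal=TimeSeries(cleaned, sampling_rate=rate, meta=dict(actions)),
                patient_id=str(row["patient_id"]), sex=str(row["sex"]),
                hemisphere=str(row.get("hemisphere", "")),
                region=str(row["region"]), state=str(row["state"]),
                age=float(row["age"]), channel=str(row["channel"]),
            )
            records.append(rec)
            report.append({"row": int(i), "status": "ok", **actions})
        except Exception as exc:  # reject the row, keep going
            report.append({"row": int(i), "status": "rejected", "reason": str(exc)})
    return records, report


@dataclass
class CohortSelection:
    region: str
    state: str
    selected: list            # ChannelRecords of the chosen patients
    female_ids: tuple
    male_ids: tuple
    mean_age_gap: float
    sd_age_gap: float
    excluded: bool = False
    reason: str = ""


def _patient_ages(records) -> dict:
    ages = {}
    for r in records:
        ages[r.patient_id] = r.age
    return ages


def _best_subsets(ages_f: dict, ages_m: dict, n: int):
    """Pick n patients per sex minimizing |mean age gap|, then |SD gap|.

    Exhaustive over all C(pool, n) pairs when both pools hold <= 12
    patients, otherwise a greedy swap descent from the age-sorted middle.
    """
    ids_f, ids_m = sorted(ages_f), sorted(ages_m)

    def stats(ids, ages):
        a = np.array([ages[i] for i in ids], float)
        return a.mean(), a.std()

    if len(ids_f) <= 12 and len(ids_m) <= 12:
        subs_f = list(itertools.combinations(ids_f, n))
        subs_m = list(itertools.combinations(ids_m, n))
        stats_f = [stats(s, ages_f) for s in subs_f]
        stats_m = [stats(s, ages_m) for s in subs_m]
        best, best_key = None, None
        for sf, stf in zip(subs_f, stats_f):
            for sm, stm in zip(subs_m, stats_m):
                key = (abs(stf[0] - stm[0]), abs(stf[1] - stm[1]))
                if best_key is None or key < best_key:
                    best_key, best = key, (sf, sm)
        return best[0], best[1], best_key

    # greedy: start from age-sorted central blocks, swap while improving
    def central(ids, ages):
        s = sorted(ids, key=lambda i: ages[i])
        start = (len(s) - n) // 2
        return list(s[start : start + n])

    cur_f, cur_m = central(ids_f, ages_f), central(ids_m, ages_m)

    def key_of(f, m):
        stf, stm = stats(f, ages_f), stats(m, ages_m)
        return (abs(stf[0] - stm[0]), abs(stf[1] - stm[1]))

    improved = True
    while improved:
        improved = False
        for ids, pool, ages in ((cur_f, ids_f, ages_f), (cur_m, ids_m, ages_m)):
            for out_i in list(ids):
                for in_i in pool:
                    if in_i in ids:
                        continue
                    cand = sorted(set(ids) - {out_i} | {in_i})
                    trial_f = cand if ids is cur_f else cur_f
                    trial_m = cand if ids is cur_m else cur_m
                    if key_of(trial_f, trial_m) < key_of(cur_f, cur_m):
                        ids[:] = cand
                        improved = True
    return tuple(cur_f), tuple(cur_m), key_of(cur_f, cur_m)


def select_cohort(records, region: str, state: str, hemisphere: str = "L",
                  n_per_sex: int = 5) -> CohortSelection:
    """Select n patients per sex in one region x state, age-matched.

    Uses only metadata (never signal content).  Regions with fewer than
    n_per_sex patients of either sex are excluded with a reason, not raised.
    """
    pool = [r for r in records
            if r.region == region and r.state == state and r.hemisphere == hemisphere]
    by_sex = {"F": {}, "M": {}}
    for r in pool:
        by_sex[r.sex][r.patient_id] = r.age
    nf, nm = len(by_sex["F"]), len(by_sex["M"])
    if nf < n_per_sex or nm < n_per_sex:
        return CohortSelection(region=region, state=state, selected=[],
                               female_ids=(), male_ids=(), mean_age_gap=np.nan,
                               sd_age_gap=np.nan, excluded=True,
                               reason=f"needs >= {n_per_sex} per sex, found F={nf}, M={nm}")
    sel_f, sel_m, (gap_mean, gap_sd) = _best_subsets(by_sex["F"], by_sex["M"], n_per_sex)
    chosen = set(sel_f) | set(sel_m)
    selected = [r for r in pool if r.patient_id in chosen]
    return CohortSelection(region=region, state=state, selected=selected,
                           female_ids=tuple(sel_f), male_ids=tuple(sel_m),
                           mean_age_gap=float(gap_mean), sd_age_gap=float(gap_sd))


@dataclass
class PipelineConfig:
    """Knobs of the group analysis; defaults follow the standard protocol."""

    D: int = 6
    q_grid: np.ndarray | None = None          # default 0.1:7:0.01
    q_window: tuple = (1.0, 7.0)
    tau_modes: tuple = ("1", "ts")
    hemisphere: str = "L"
    n_per_sex: int = 5
    band: tuple = (10.0, 40.0)
    adf_alpha: float = 0.05
    run_adf: bool = True
    drop_nonstationary: bool = False
    analyses: tuple = ("spectral", "curves")
    sd_mult: float = 1.0
    min_run: float = 0.5


@dataclass
class GroupAnalysisResult:
    table: pd.DataFrame
    tau_s: dict               # state -> (tau_s float, tau int used)
    cells: dict               # (state, region) -> per-cell detail dict
    coincidence: dict         # co-occurrence counts of k-flag with tau flags
    config: PipelineConfig


def _cell_curves(chans, D, tau, q_grid):
    curves = []
    for r in chans:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = ordinal_distribution(r.signal, D, tau)
        curves.append(ec_curve(dist, q_grid, label=f"{r.sex}:{r.channel}"))
    return curves


def run_group_analysis(records, config: PipelineConfig | None = None) -> GroupAnalysisResult:
    """Full group comparison over every region x state cell.

    Per cell: cohort selection, ADF screen, spectral fits + notch flag, and
    (per tau mode) per-channel curves, sex-group stats and the ellipse
    separation flag.  tau_s per state is the characteristic time over that
    state's selected channels, rounded to an integer delay >= 1.  Failures
    are isolated per cell (recorded as missing).
    """
    config = config or PipelineConfig()
    q_grid = config.q_grid
    regions = sorted({r.region for r in records})
    states = [s for s in ("W", "N2", "N3", "R") if any(r.state == s for r in records)]

    cohorts = {}
    for state in states:
        for region in regions:
            cohorts[(state, region)] = select_cohort(
                records, region, state, config.hemisphere, config.n_per_sex)

    # state-level characteristic time from all selected channels of the state
    tau_s: dict = {}
    for state in states:
        chans = [r.signal for (s, _), c in cohorts.items() if s == state and not c.excluded
                 for r in c.selected]
        if chans and "curves" in config.analyses and "ts" in config.tau_modes:
            ts, _, _ = characteristic_time(chans)
            tau_s[state] = (float(ts), max(1, int(round(ts))))
        else:
            tau_s[state] = (np.nan, 1)

    rows, cells = [], {}
    for state in states:
        for region in regions:
            cohort = cohorts[(state, region)]
            row = {"state": state, "region": region,
                   "flag_k": np.nan, "flag_tau1": np.nan, "flag_taus": np.nan,
                   "n_F": 0, "n_M": 0, "tau_s": tau_s[state][0],
                   "tau_s_int": tau_s[state][1],
                   "q_window": f"{config.q_window[0]}:{config.q_window[1]}"}
            detail = {"cohort": cohort}
            if cohort.excluded:
                row["status"] = f"excluded: {cohort.reason}"
                rows.append(row); cells[(state, region)] = detail
                continue
            chans = cohort.selected
            row["n_F"] = sum(1 for r in chans if r.sex == "F")
            row["n_M"] = sum(1 for r in chans if r.sex == "M")
            try:
                if config.run_adf:
                    adf = {r.channel: adf_screen(r.signal, config.adf_alpha) for r in chans}
                    detail["adf_nonstationary"] = [c for c, a in adf.items() if not a.stationary]
                    if config.drop_nonstationary:
                        chans = [r for r in chans
                                 if adf[r.channel].stationary]

                if "spectral" in config.analyses:
                    fits = {}
                    for r in chans:
                        freqs, psd, _ = welch_psd(r.signal)
                        fits[r.channel] = (r.sex, powerlaw_fit(freqs, psd, *config.band))
                    ks_f = [f.k for sex, f in fits.values() if sex == "F"]
                    ks_m = [f.k for sex, f in fits.values() if sex == "M"]
                    notch = notch_compare(ks_f, ks_m)
                    row["flag_k"] = notch.flag
                    detail["fits"] = fits
                    detail["notch"] = notch

                if "curves" in config.analyses:
                    for mode in config.tau_modes:
                        tau = 1 if mode == "1" else tau_s[state][1]
                        curves = _cell_curves(chans, config.D, tau, q_grid)
                        stats = {
                            sex: group_stats([c for c, r in zip(curves, chans)
                                              if r.sex == sex], label=sex)
                            for sex in ("F", "M")
                        }
                        sep = ellipse_separation(stats["F"], stats["M"],
                                                 q_window=config.q_window,
                                                 sd_mult=config.sd_mult,
                                                 min_run=config.min_run)
                        key = "flag_tau1" if mode == "1" else "flag_taus"
                        row[key] = sep.flag
                        detail[f"curves_tau{tau}"] = curves
                        detail[f"stats_tau{tau}"] = stats
                        detail[f"separation_{mode}"] = sep
                row["status"] = "ok"
            except Exception as exc:
                row["status"] = f"failed: {exc}"
            rows.append(row)
            cells[(state, region)] = detail

    table = pd.DataFrame(rows)
    coincidence = {
        "k_and_tau1": int(((table["flag_k"] == 1) & (table["flag_tau1"] == 1)).sum()),
        "k_and_taus": int(((table["flag_k"] == 1) & (table["flag_taus"] == 1)).sum()),
    }
    return GroupAnalysisResult(table=table, tau_s=tau_s, cells=cells,
                               coincidence=coincidence, config=config)


def write_report(result: GroupAnalysisResult, outdir: str | Path) -> dict:
    """Write the comparison table (CSV) and a JSON bundle of group stats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / "comparison_table.csv"
    result.table.to_csv(table_path, index=False)

    summary = {
        "tau_s": {s: {"tau_s": (None if np.isnan(v[0]) else v[0]), "tau_used": v[1]}
                  for s, v in result.tau_s.items()},
        "coincidence": result.coincidence,
        "flags_per_state": {
            s: {col: int(pd.to_numeric(g[col], errors="coerce").fillna(0).sum())
                for col in ("flag_k", "flag_tau1", "flag_taus")}
            for s, g in result.table.groupby("state")
        },
    }
    stats = {}
    for (state, region), detail in result.cells.items():
        key = f"{state}|{region}"
        entry = {}
        if "notch" in detail:
            n = detail["notch"]
            entry["k_notch"] = {
                "F": {"median": n.group_a.median, "half_width": n.group_a.half_width,
                      "n": n.group_a.n},
                "M": {"median": n.group_b.median, "half_width": n.group_b.half_width,
                      "n": n.group_b.n},
                "flag": n.flag,
            }
        for dkey, val in detail.items():
            if dkey.startswith("stats_tau"):
                entry[dkey] = {
                    sex: {"mean_H": st.mean_H.tolist(), "mean_C": st.mean_C.tolist(),
                          "sd_H": st.sd_H.tolist(), "sd_C": st.sd_C.tolist(), "n": st.n}
                    for sex, st in val.items()
                }
        stats[key] = entry
    stats_path = outdir / "group_stats.json"
    stats_path.write_text(json.dumps({"summary": summary, "cells": stats}, indent=2))
    return {"table": table_path, "stats": stats_path}
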
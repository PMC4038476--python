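"""File-based pipeline stages: simulate -> fit -> detect -> classify -> cohort.

Each stage reads and writes the plain-text formats of :mod:`touchzap.io`
inside a cohort directory laid out as::

    outdir/
      truth.csv                  ground-truth parameter table
      run.log                    config echo + seed (no timestamps)
      cell_0000/
        session.tsv              approach/access log (+ .annotations.tsv)
        trace_00.tsv ...         IV step sweeps

The CLI wraps these functions; they are equally usable from Python.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import io as tzio
from .circuit import Cohort, CohortConfig, simulate_cohort
from .classify import ClassifyConfig, QCConfig, CellRecord, classify_cell, qc_evaluate, spike_metrics
from .core import StepProtocol
from .events import DetectionConfig, analyze_session
from .passive import CellPassive, FitConfig, fit_cell
from .stats import l_rel, summarize, two_sample_t


def config_digest(config) -> str:
    """Stable short hash of a config dataclass, for run logs."""
    try:
        payload = json.dumps(asdict(config), sort_keys=True, default=str)
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate_to_dir(config: CohortConfig, seed: int, outdir) -> Cohort:
    """Simulate a cohort and write it out as TSV/CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config, seed)
    for cell in cohort.cells:
        cdir = outdir / cell.cell_id
        cdir.mkdir(exist_ok=True)
        if cell.session is not None:
            tzio.write_session(cell.session, cdir / "session.tsv")
        for j, trace in enumerate(cell.traces):
            tzio.write_trace(trace, cdir / f"trace_{j:02d}.tsv")
    tzio.write_records(cohort.truth, outdir / "truth.csv")
    (outdir / "run.log").write_text(
        f"command: simulate\nseed: {seed}\nconfig_hash: {config_digest(config)}\n"
        f"n_cells: {config.n_cells}\n"
    )
    return cohort


def _cell_dirs(indir):
    return sorted(p for p in Path(indir).iterdir() if p.is_dir() and p.name.startswith("cell_"))


def fit_dir(indir, config: FitConfig = FitConfig()) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Passive fits for every cell directory.

    Returns (per-cell table, per-trace table); cells whose every sweep fails
    the screen get a row with status 'rejected' rather than aborting the run.
    """
    cell_rows, trace_rows = [], []
    for cdir in _cell_dirs(indir):
        traces = [tzio.read_trace(p) for p in sorted(cdir.glob("trace_*.tsv"))]
        traces = [tr for tr in traces if isinstance(tr.protocol, StepProtocol)]
        cell_id = cdir.name
        try:
            cp = fit_cell(traces, config)
        except ValueError as exc:
            cell_rows.append(dict(cell_id=cell_id, status="rejected", reason=str(exc)))
            continue
        cell_rows.append(dict(
            cell_id=cell_id, status="ok", reason="",
            V_rest=cp.V_rest, V_ss=cp.V_ss, tau0=cp.tau0, R_in=cp.R_in,
            R_a_error=cp.R_a_error, R_a_mean=cp.R_a_mean, dRa_dt=cp.dRa_dt,
            n_traces=cp.n_traces, n_rejected=len(cp.rejections),
        ))
        for res in cp.results:
            trace_rows.append(dict(
                cell_id=cell_id, rec_time_s=res.rec_time_s,
                V_rest=res.V_rest, V_ss=res.V_ss, V_O=res.V_O,
                tau0=res.tau0, R_in=res.R_in, R_a_error=res.R_a_error,
                R_a_total=res.R_a_total, amplitude_na=res.amplitude_na,
                r2_log_fit=res.r2_log_fit, n_points=res.n_points,
            ))
    return pd.DataFrame(cell_rows), pd.DataFrame(trace_rows)


def detect_dir(indir, config: DetectionConfig = DetectionConfig()) -> pd.DataFrame:
    """Event detection + endpoint classification for every session log."""
    rows = []
    for cdir in _cell_dirs(indir):
        spath = cdir / "session.tsv"
        if not spath.exists():
            continue
        log = tzio.read_session(spath)
        call = analyze_session(log, config)
        tzio.write_events(log.events, cdir / "events.tsv")
        rows.append(dict(
            cell_id=cdir.name,
            endpoint=call.endpoint,
            n_zaps=len(call.zaps),
            T_zap=call.T_zap if call.T_zap is not None else np.nan,
            V_zap=call.V_zap if call.V_zap is not None else np.nan,
            flags="|".join(sorted(call.flags)),
            reason=call.reason,
        ))
    return pd.DataFrame(rows)


def classify_dir(
    indir,
    fits: pd.DataFrame,
    trace_fits: pd.DataFrame,
    endpoints: Optional[pd.DataFrame] = None,
    config: ClassifyConfig = ClassifyConfig(),
    qc_config: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Build one CellRecord row per fitted cell (classification, spike
    metrics, QC flags, endpoint)."""
    fits = fits.set_index("cell_id")
    ep = endpoints.set_index("cell_id") if endpoints is not None and len(endpoints) else None
    rows = []
    for cdir in _cell_dirs(indir):
        cell_id = cdir.name
        if cell_id not in fits.index or fits.loc[cell_id, "status"] != "ok":
            continue
        frow = fits.loc[cell_id]
        traces = [tzio.read_trace(p) for p in sorted(cdir.glob("trace_*.tsv"))]
        sub = trace_fits[trace_fits.cell_id == cell_id].sort_values("rec_time_s")
        passive = CellPassive(
            V_rest=frow.V_rest, V_ss=frow.V_ss, tau0=frow.tau0,
            R_a_error=frow.R_a_error, R_in=frow.R_in,
            R_a_mean=frow.R_a_mean, dRa_dt=frow.dRa_dt, n_traces=int(frow.n_traces),
        )
        cls = classify_cell(traces, passive, config)
        dvdt, vpeak = float("nan"), float("nan")
        if cls == "neuron":
            per_spike = []
            for tr in traces:
                try:
                    per_spike.append(spike_metrics(tr, v_rest=passive.V_rest, config=config))
                except ValueError:
                    pass
            if per_spike:
                dvdt = float(np.mean([m[0] for m in per_spike]))
                vpeak = float(np.mean([m[1] for m in per_spike]))
        flags = qc_evaluate(
            ra_series=sub.R_a_total.tolist(),
            vrest_series=sub.V_rest.tolist(),
            r_in=frow.R_in,
            config=qc_config,
        )
        meta = traces[0].meta if traces else {}
        endpoint = ""
        if ep is not None and cell_id in ep.index:
            endpoint = str(ep.loc[cell_id, "endpoint"])
        rec = CellRecord(
            cell_id=cell_id,
            species=str(meta.get("species", "")),
            cell_class=cls,
            passive=passive,
            spike_dvdt_max=dvdt,
            spike_v_peak=vpeak,
            endpoint=endpoint,
            qc_flags=flags,
            duration_min=(sub.rec_time_s.max() / 60.0) if len(sub) else float("nan"),
            depth_um=float(meta.get("depth_um", float("nan"))),
        )
        rows.append(rec.to_row())
    return pd.DataFrame(rows)


def cohort_report(records: pd.DataFrame) -> Tuple[str, pd.DataFrame]:
    """Cohort summary text + summary table.

    Group comparisons are per-variable two-sample t tests (no multivariate
    test is attempted), which the report header states.
    """
    lines = [
        "cohort summary",
        "==============",
        "group comparisons: per-variable two-sample Student t tests",
        "(pairwise tests stand in for any multivariate comparison)",
        "",
    ]
    counts = records.groupby(["cell_class", "endpoint"]).size().unstack(fill_value=0)
    lines.append("recordings by class and endpoint:")
    lines.append(counts.to_string())
    lines.append("")
    for cls, grp in records.groupby("cell_class"):
        total = len(grp)
        by_ep = grp.groupby("endpoint").size()
        props = ", ".join(f"{ep}: {100 * n / total:.0f}%" for ep, n in by_ep.items())
        lines.append(f"{cls} endpoint mix (n={total}): {props}")
    lines.append("")

    value_cols = [c for c in ("tau0", "R_in", "V_rest", "R_a", "dRa_dt", "spike_dvdt_max", "spike_v_peak")
                  if c in records.columns]
    summary = summarize(records, value_cols, by=("cell_class",))
    lines.append("parameters by cell class (mean±SD (n)):")
    lines.append(summary[["cell_class"] + value_cols].to_string(index=False))
    lines.append("")

    ok = records[records.R_in > 0]
    if len(ok) >= 2 and ok.cell_class.nunique() >= 1:
        lr = l_rel(ok.R_in.to_numpy(), ok.cell_class.tolist())
        by_class = pd.Series(lr.values.to_numpy(), index=ok.index).groupby(ok.cell_class).mean()
        lines.append("relative cell size L_rel (class mean = 1 by construction):")
        lines.append(by_class.to_string())
        lines.append("")

    neurons = records[records.cell_class == "neuron"]
    glia = records[records.cell_class == "glia"]
    if len(neurons) >= 2 and len(glia) >= 2:
        lines.append("neuron vs glia (two-tailed Student t):")
        for col in ("V_rest", "R_in", "tau0"):
            if col in records.columns:
                t, df, p = two_sample_t(neurons[col].dropna(), glia[col].dropna())
                lines.append(f"  {col}: t={t:.3f}, df={df:.0f}, p={p:.3g}")
        lines.append("")
    return "\n".join(lines) + "\n", summary


__all__ = [
    "config_digest",
    "simulate_to_dir",
    "fit_dir",
    "detect_dir",
    "classify_dir",
    "cohort_report",
]
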
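"""Full-study report: simple-order fits, Arrhenius table, network fits.

``run_report`` consumes a directory of timecourse CSVs (one per
temperature, real or synthetic), runs every analysis stage, and returns a
JSON-serializable bundle mirroring the layout of a kinetic-study results
section: per-response rate constants at each order with R^2, activation
energies across temperatures, and the multi-response network estimates
with intervals and indeterminacy flags.  Per-response failures are
recorded in place rather than aborting the run.
"""

from __future__ import annotations

import glob
import json
import os
from pathlib import Path

from . import __version__
from .datamodel import RunConfig, Timecourse, read_timecourse
from .errors import MrkinetError, ValidationError
from .estimation import fit_network
from .simple_kinetics import arrhenius_fit, fit_all_orders, select_model

FILE_PATTERN = "*.csv"


def load_data_dir(data_dir: str | os.PathLike) -> dict[float, Timecourse]:
    paths = sorted(glob.glob(str(Path(data_dir) / FILE_PATTERN)))
    if not paths:
        raise ValidationError(
            f"no timecourse files matching {FILE_PATTERN!r} in {data_dir}"
        )
    out = {}
    for p in paths:
        tc = read_timecourse(p)
        out[tc.temperature] = tc
    return out


def run_report(config: RunConfig, data_dir: str | os.PathLike,
               fit_network_stage: bool = True) -> dict:
    """Run all analysis stages over a directory of timecourse CSVs."""
    data = load_data_dir(data_dir)
    temps = sorted(data)

    simple: dict[str, dict] = {}
    response_names = sorted({n for tc in data.values() for n in tc.responses})
    for name in response_names:
        per_temp = {}
        for temp in temps:
            tc = data[temp]
            if name not in tc.responses:
                continue
            series = tc.responses[name]
            fits = fit_all_orders(tc.times, series.values, name)
            if not fits:
                per_temp[f"{temp:g}"] = {"error": "no order fits this series"}
                continue
            best = select_model(fits)
            per_temp[f"{temp:g}"] = {
                "fits": [{"order": f.order, "k": f.k, "C0_hat": f.C0_hat,
                          "r_squared": f.r_squared} for f in fits],
                "selected_order": best.order,
            }
        simple[name] = per_temp

    arrhenius: dict[str, dict] = {}
    for name, per_temp in simple.items():
        pairs = []
        for temp in temps:
            cell = per_temp.get(f"{temp:g}")
            if not cell or "fits" not in cell:
                continue
            zero = next((f for f in cell["fits"] if f["order"] == 0), None)
            if zero is not None and zero["k"] != 0:
                pairs.append((zero["k"], temp))
        if len(pairs) < 2:
            arrhenius[name] = {"error": "needs zero-order k at >= 2 temperatures"}
            continue
        try:
            res = arrhenius_fit(pairs)
            arrhenius[name] = {"Ea_kJ_per_mol": res.Ea,
                               "Ea_stderr": res.Ea_stderr,
                               "lnA": res.lnA, "r_squared": res.r_squared,
                               "n_points": res.n_points}
        except MrkinetError as exc:
            arrhenius[name] = {"error": str(exc)}

    network: dict[str, dict] = {}
    if fit_network_stage:
        for temp in temps:
            try:
                fit = fit_network(data[temp], config)
                network[f"{temp:g}"] = {
                    "estimates": fit.estimates,
                    "half_widths": fit.half_widths,
                    "indeterminate": fit.indeterminate,
                    "objective": fit.objective,
                    "converged": fit.converged,
                }
            except MrkinetError as exc:
                network[f"{temp:g}"] = {"error": str(exc)}

    return {
        "provenance": {
            "package": "mrkinet",
            "version": __version__,
            "seed": int(config.seed),
            "multistarts": config.multistarts,
            "rtol": config.rtol,
            "temperatures": [f"{t:g}" for t in temps],
        },
        "simple_kinetics": simple,
        "arrhenius": arrhenius,
        "network_fits": network,
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_markdown(report: dict) -> str:
    lines = ["# Kinetic analysis report", ""]
    lines.append("## Arrhenius activation energies")
    lines.append("")
    lines.append("| response | Ea (kJ/mol) | stderr | R^2 |")
    lines.append("|---|---|---|---|")
    for name, cell in sorted(report["arrhenius"].items()):
        if "error" in cell:
            lines.append(f"| {name} | failed: {cell['error']} | | |")
        else:
            lines.append(
                f"| {name} | {cell['Ea_kJ_per_mol']:.3f} | "
                f"{cell['Ea_stderr']:.3f} | {cell['r_squared']:.3f} |"
            )
    lines.append("")
    if report["network_fits"]:
        lines.append("## Network rate constants")
        lines.append("")
        temps = sorted(report["network_fits"])
        header = "| parameter | " + " | ".join(f"{t} C" for t in temps) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(temps) + 1))
        params = [f"k{i}" for i in range(1, 16)]
        for p in params:
            row = [p]
            for t in temps:
                cell = report["network_fits"][t]
                if "error" in cell:
                    row.append("failed")
                else:
                    est = cell["estimates"][p]
                    tag = " *ind" if cell["indeterminate"][p] else ""
                    row.append(f"{est:.4g}{tag}")
            lines.append("| " + " | ".join(row) + " |")
        lines.append("")
    return "\n".join(lines)
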
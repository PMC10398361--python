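"""Uncertainty machinery and the analysis driver.

Block averaging provides the standard error behind every reported "mean +-"
value: correlated per-frame series are split into contiguous blocks and the
spread of block means estimates the error of the overall mean.  Replicate
simulations are aggregated with the convention used for duplicate runs:
half-range for two replicates, standard error for three or more, single-run
block standard error otherwise.

``run_analysis`` executes the analyses requested by an :class:`AnalysisConfig`
in order and writes TSV series, JSON summaries and a plain-text table.  All
defaults applied are echoed into the output so a report is self-describing,
and JSON is written with sorted keys and fixed formatting so identical inputs
give byte-identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "block_average",
    "aggregate_replicates",
    "AnalysisConfig",
    "SummaryRow",
    "run_analysis",
]


def block_average(series: Sequence[float], n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block-averaged standard error of a per-frame series.

    The series is split into ``n_blocks`` contiguous equal blocks (any
    remainder is dropped from the front); the standard error is the sample
    standard deviation of the block means divided by sqrt(n_blocks).
    """
    values = np.asarray(series, dtype=float)
    if len(values) < n_blocks:
        raise ValueError(f"series of length {len(values)} is shorter than {n_blocks} blocks")
    if n_blocks < 1:
        raise ValueError("need at least one block")
    remainder = len(values) % n_blocks
    used = values[remainder:]
    blocks = used.reshape(n_blocks, -1)
    block_means = blocks.mean(axis=1)
    mean = float(used.mean())
    if n_blocks == 1:
        return mean, 0.0
    stderr = float(block_means.std(ddof=1) / math.sqrt(n_blocks))
    return mean, stderr


def aggregate_replicates(
    replicate_means: Sequence[float], block_stderr: float | None = None
) -> tuple[float, float, int]:
    """Aggregate per-replicate means into (mean, uncertainty, n_replicates).

    Uncertainty convention: block standard error for a single replicate
    (``block_stderr`` passthrough), half the range for duplicates, standard
    error of the mean for three or more.
    """
    means = np.asarray(replicate_means, dtype=float)
    n = len(means)
    if n == 0:
        raise ValueError("no replicates")
    mean = float(means.mean())
    if n == 1:
        unc = float(block_stderr) if block_stderr is not None else float("nan")
    elif n == 2:
        unc = float(np.ptp(means) / 2.0)
    else:
        unc = float(means.std(ddof=1) / math.sqrt(n))
    return mean, unc, n


@dataclass
class SummaryRow:
    system: str
    observable: str
    mean: float
    uncertainty: float
    units: str
    n_replicates: int


_DEFAULT_PARAMETERS: dict[str, Any] = {
    "temperature": 313.0,  # K
    "v_water": 30.53,  # Angstrom^3, TIP3P
    "equilibration_fraction": 0.05,
    "n_blocks": 5,
    "stride": 1,
    "density_bin_width": 0.5,  # Angstrom
    "hbond_max_distance": 3.0,  # Angstrom, donor-acceptor
    "hbond_min_angle": 135.0,  # degrees, D-H...A
    "contact_cutoff": 2.8,  # Angstrom, metal coordination scale
    "ring_cutoffs": [4.5],
}


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run.

    ``selections`` maps labels to lists of (residue-name pattern, atom-name
    pattern) pairs.  ``parameters`` overrides the documented defaults.
    """

    trajectories: list[str]
    selections: dict[str, list[tuple[str, str]]]
    analyses: list[str]
    output_dir: str
    system_label: str = "system"
    parameters: dict[str, Any] = field(default_factory=dict)
    chains: dict[str, dict[str, Any]] = field(default_factory=dict)
    peptide: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["selections"] = {
            k: [tuple(p) for p in v] for k, v in raw.get("selections", {}).items()
        }
        return cls(**raw)

    def param(self, key: str) -> Any:
        return self.parameters.get(key, _DEFAULT_PARAMETERS[key])

    def resolved_parameters(self) -> dict[str, Any]:
        out = dict(_DEFAULT_PARAMETERS)
        out.update(self.parameters)
        return out


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, allow_nan=True) + "\n")


def _series_tsv(path: Path, header: Sequence[str], columns: Sequence[np.ndarray]) -> None:
    lines = ["\t".join(header)]
    for row in zip(*columns):
        lines.append("\t".join(f"{v:.6f}" if isinstance(v, float) else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the requested analyses and write TSV/JSON reports.

    Returns the summary dictionary that is also written to
    ``<output_dir>/summary.json``.  Every reported value is the corresponding
    module-level operation's result; the reporting layer never recomputes.
    """
    # imported here: the metric modules use block_average from this module
    from bilayerlab import core, helix, interactions, metrics

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    params = config.resolved_parameters()
    log.append(f"parameters: {json.dumps(params, sort_keys=True)}")

    trajs = []
    for p in config.trajectories:
        traj = core.read_trajectory(p, selection_config=config.selections)
        trajs.append(traj)
        log.append(f"trajectory {p}: {traj.n_frames} frames, {traj.topology.n_atoms} atoms")
    for label, sel in trajs[0].selections.items():
        log.append(f"selection {label!r}: {len(sel)} atoms")

    def get_sel(traj, label: str):
        if label not in traj.selections:
            raise KeyError(f"analysis requires selection {label!r}, not defined in config")
        return traj.selections[label]

    eq_frac = params["equilibration_fraction"]
    n_blocks = params["n_blocks"]
    summary: dict[str, Any] = {
        "system": config.system_label,
        "parameters": params,
        "observables": {},
    }

    def record(name: str, per_replicate: list[Any], units: str) -> None:
        if isinstance(per_replicate[0], metrics.BilayerMetricSeries):
            means = [s.mean for s in per_replicate]
            mean, unc, n = aggregate_replicates(means, block_stderr=per_replicate[0].stderr)
        else:
            means = [float(v) for v in per_replicate]
            mean, unc, n = aggregate_replicates(means)
        summary["observables"][name] = {
            "mean": round(mean, 6),
            "uncertainty": round(unc, 6) if not math.isnan(unc) else None,
            "units": units,
            "n_replicates": n,
        }

    try:
        for analysis in config.analyses:
            log.append(f"running analysis: {analysis}")
            if analysis == "area_per_lipid":
                m = int(params["m_lipid"])
                series = [
                    metrics.area_per_lipid(
                        t, m, discard_fraction=eq_frac, n_blocks=n_blocks
                    )
                    for t in trajs
                ]
                _series_tsv(
                    out_dir / "area_per_lipid.tsv",
                    ["frame", "A_L"],
                    [np.arange(len(series[0].per_frame)), series[0].per_frame],
                )
                record("A_L", series, "Angstrom^2")
            elif analysis == "volume_per_lipid":
                series = [
                    metrics.volume_per_lipid(
                        t,
                        int(params["n_waters"]),
                        int(params["n_lipids"]),
                        v_w=params["v_water"],
                        discard_fraction=eq_frac,
                        n_blocks=n_blocks,
                    )
                    for t in trajs
                ]
                record("V_L", series, "Angstrom^3")
            elif analysis == "compressibility":
                m = int(params["m_lipid"])
                vals = []
                for t in trajs:
                    areas = metrics.area_per_lipid(t, m, discard_fraction=eq_frac, n_blocks=n_blocks)
                    res = metrics.area_compressibility(areas, params["temperature"], m)
                    vals.append(res.K_A)
                record("K_A", vals, "mN/m")
            elif analysis in ("thickness_pp", "thickness_c2"):
                label = "phosphate" if analysis == "thickness_pp" else "c2"
                series = []
                for t in trajs:
                    leaflets = core.assign_leaflets(t.frames[0], get_sel(t, "phosphate"))
                    series.append(
                        metrics.bilayer_thickness(
                            t, get_sel(t, label), leaflets,
                            discard_fraction=eq_frac, n_blocks=n_blocks,
                        )
                    )
                record("h_PP" if analysis == "thickness_pp" else "h_C2C2", series, "Angstrom")
            elif analysis == "density":
                groups = {
                    lbl: get_sel(trajs[0], lbl)
                    for lbl in config.parameters.get(
                        "density_groups", ["phosphate", "ch2", "ch3", "pep_backbone"]
                    )
                    if lbl in trajs[0].selections and len(trajs[0].selections[lbl]) > 0
                }
                profile = metrics.electron_density_profile(
                    trajs[0], groups, bin_width=params["density_bin_width"],
                    center_sel=get_sel(trajs[0], "phosphate"),
                )
                cols = [profile.bin_centers] + [profile.densities[g] for g in profile.densities]
                _series_tsv(out_dir / "density.tsv", ["z"] + list(profile.densities), cols)
                summary["observables"]["density_groups"] = sorted(profile.densities)
            elif analysis == "order_parameters":
                for t in trajs:
                    chain_map = {}
                    for chain_label, spec_ in config.chains.items():
                        chain_map[chain_label] = metrics.chain_triples_from_names(
                            t.topology, spec_["residue"], spec_["carbons"]
                        )
                    profiles = metrics.order_parameters(t, chain_map)
                    for chain_label, prof in profiles.items():
                        _series_tsv(
                            out_dir / f"scd_{chain_label}.tsv",
                            ["carbon_index", "abs_scd"],
                            [prof.carbon_index.astype(float), prof.abs_scd],
                        )
                        summary["observables"][f"S_CD_{chain_label}"] = {
                            "per_carbon": [round(float(v), 6) for v in prof.scd],
                            "units": "",
                            "n_replicates": 1,
                        }
                    break  # chains reported for the first replicate
            elif analysis == "orientation":
                pep = config.peptide
                reference = helix.build_reference_helix(int(pep["n_residues"]))
                segments = {k: tuple(v) for k, v in pep["segments"].items()}
                for t in trajs:
                    result = helix.orientation_series(
                        t,
                        reference,
                        segments,
                        leaflet_P=get_sel(t, "phosphate"),
                        residue_names=tuple(pep.get("residue_names", ("ALA",))),
                        stride=int(params["stride"]),
                    )
                    rows = []
                    for label, series in result.items():
                        summary["observables"][f"tau_{label}"] = {
                            "mean": round(series.mean_tau, 6), "units": "degrees",
                        }
                        summary["observables"][f"rho_{label}"] = {
                            "mean": round(series.mean_rho, 6), "units": "degrees",
                        }
                        summary["observables"][f"z_{label}"] = {
                            "mean": round(series.mean_z, 6), "units": "Angstrom",
                        }
                        for i in range(len(series.tau)):
                            rows.append(
                                (i, label, series.tau[i], series.rho[i], series.z[i], series.fit_rmsd[i])
                            )
                    lines = ["frame\tsegment\ttau\trho\tz\trmsd"]
                    for r in rows:
                        lines.append(
                            f"{r[0]}\t{r[1]}\t{r[2]:.4f}\t{r[3]:.4f}\t{r[4]:.4f}\t{r[5]:.6f}"
                        )
                    (out_dir / "orientation.tsv").write_text("\n".join(lines) + "\n")
                    if {"N", "C"} <= set(result):
                        summary["observables"]["delta_tau"] = {
                            "mean": round(result["N"].mean_tau - result["C"].mean_tau, 6),
                            "units": "degrees",
                        }
                        summary["observables"]["delta_rho"] = {
                            "mean": round(
                                (result["N"].mean_rho - result["C"].mean_rho + 180.0) % 360.0 - 180.0, 6
                            ),
                            "units": "degrees",
                        }
                        summary["observables"]["delta_z"] = {
                            "mean": round(result["N"].mean_z - result["C"].mean_z, 6),
                            "units": "Angstrom",
                        }
                    break
            elif analysis == "chain_reversal":
                for t in trajs:
                    leaflets = core.assign_leaflets(t.frames[0], get_sel(t, "phosphate"))
                    result = interactions.detect_chain_reversal(
                        t, get_sel(t, "oxpl_terminal"), leaflets, get_sel(t, "c2")
                    )
                    summary["observables"]["reversal_fraction"] = {
                        "mean": round(result.fraction, 6), "units": "",
                    }
                    break
            elif analysis == "contacts":
                for t in trajs:
                    frac = interactions.contact_occupancy(
                        t, get_sel(t, "contact_a"), get_sel(t, "contact_b"),
                        cutoff=params["contact_cutoff"],
                    )
                    summary["observables"]["contact_occupancy"] = {
                        "mean": round(frac, 6), "units": "",
                    }
                    break
            elif analysis == "hbonds":
                for t in trajs:
                    donors = interactions.donor_pairs_from_selections(
                        t.topology, get_sel(t, "hbond_donors"), get_sel(t, "hbond_hydrogens")
                    )
                    crit = interactions.HBondCriteria(
                        max_DA_distance=params["hbond_max_distance"],
                        min_DHA_angle=params["hbond_min_angle"],
                    )
                    series = interactions.count_hydrogen_bonds(
                        t, donors, get_sel(t, "hbond_acceptors"), crit
                    )
                    record("hbond_count", [series], "bonds")
                    break
            else:
                raise ValueError(f"unknown analysis {analysis!r}")
    except KeyError as exc:
        raise RuntimeError(f"analysis aborted: missing selection or parameter: {exc}") from exc

    _dump_json(summary, out_dir / "summary.json")
    (out_dir / "analysis.log").write_text("\n".join(log) + "\n")
    table_lines = [f"{'observable':<22}{'mean':>14}{'+-':>12}  units"]
    for name, entry in sorted(summary["observables"].items()):
        if isinstance(entry, dict) and "mean" in entry:
            unc = entry.get("uncertainty")
            unc_s = f"{unc:.4f}" if isinstance(unc, (int, float)) and unc is not None else "-"
            table_lines.append(
                f"{name:<22}{entry['mean']:>14.4f}{unc_s:>12}  {entry.get('units', '')}"
            )
    (out_dir / "summary.txt").write_text("\n".join(table_lines) + "\n")
    return summary
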
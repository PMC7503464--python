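"""CSV/JSON/YAML readers and writers for every pipeline stage.

Interchange formats are plain UTF-8 CSV with explicit headers:

* transient: ``time_s,intensity``
* manifest: ``sample_id,enzyme_uM,ligand_uM,replicate,file``
* spectrum: ``wavelength_nm,intensity``
* melt: ``temperature_C,ellipticity``
* activity: ``time_s,A340``
* fit results: ``sample_id,k_fast,k_fast_se,k_slow,k_slow_se,amp_fast,amp_slow,baseline,rms,converged``

Scenario and analysis configuration round-trip through YAML or JSON; the
binding block uses the keys ``kd_uM``, ``delta_H_kcal_mol`` and ``T_ref_C``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .binding import BindingParameters
from .equilibrium import SpectrumRecord
from .kinetics import KineticsSummary
from .synthetic import KineticScenario, generate_reference_transient, generate_transient
from .transients import ExpFitResult, TransientRecord

__all__ = [
    "read_transient_csv", "write_transient_csv",
    "read_spectrum_csv", "write_spectrum_csv",
    "read_manifest", "write_manifest",
    "fit_results_to_frame", "read_fit_results",
    "summary_to_frame",
    "scenario_to_dict", "scenario_from_dict",
    "binding_from_dict", "binding_to_dict",
    "load_config", "simulate_dataset", "replicate_seeds",
]


def write_transient_csv(record: TransientRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": record.time, "intensity": record.intensity}).to_csv(
        path, index=False)


def read_transient_csv(path: str | Path, **metadata) -> TransientRecord:
    df = pd.read_csv(path)
    return TransientRecord(time=df["time_s"].to_numpy(),
                           intensity=df["intensity"].to_numpy(), **metadata)


def write_spectrum_csv(record: SpectrumRecord, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": record.wavelength,
                  "intensity": record.intensity}).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, **metadata) -> SpectrumRecord:
    df = pd.read_csv(path)
    return SpectrumRecord(wavelength=df["wavelength_nm"].to_numpy(),
                          intensity=df["intensity"].to_numpy(), **metadata)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def fit_results_to_frame(fits: Iterable[ExpFitResult],
                         sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    fits = list(fits)
    if sample_ids is None:
        sample_ids = [f.label or f"sample{i}" for i, f in enumerate(fits)]
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "enzyme_uM": [f.enzyme_total for f in fits],
        "ligand_uM": [f.ligand_total for f in fits],
        "replicate": [f.replicate for f in fits],
        "k_fast": [f.k_fast for f in fits],
        "k_fast_se": [f.k_fast_se for f in fits],
        "k_slow": [f.k_slow for f in fits],
        "k_slow_se": [f.k_slow_se for f in fits],
        "amp_fast": [f.amp_fast for f in fits],
        "amp_slow": [f.amp_slow for f in fits],
        "baseline": [f.baseline for f in fits],
        "rms": [f.rms for f in fits],
        "converged": [f.converged for f in fits],
    })


def read_fit_results(path: str | Path) -> list[ExpFitResult]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(ExpFitResult(
            k_fast=row["k_fast"], k_slow=row["k_slow"],
            amp_fast=row["amp_fast"], amp_slow=row["amp_slow"],
            baseline=row["baseline"],
            k_fast_se=row["k_fast_se"], k_slow_se=row["k_slow_se"],
            amp_fast_se=float("nan"), amp_slow_se=float("nan"),
            baseline_se=float("nan"),
            rms=row["rms"], converged=bool(row["converged"]),
            enzyme_total=row["enzyme_uM"], ligand_total=row["ligand_uM"],
            replicate=int(row["replicate"]), label=str(row["sample_id"]),
        ))
    return out


def summary_to_frame(summaries: Iterable[KineticsSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "enzyme": s.label,
            "k_on": s.k_on, "k_on_se": s.k_on_se,
            "k_off": s.k_off, "k_off_se": s.k_off_se,
            "kd_tjump": s.kd_tjump, "kd_itc": s.kd_itc, "kd_ratio": s.kd_ratio,
            "r_fast": s.fast_test.r, "r_slow": s.slow_test.r,
            "verdict_fast": s.fast_test.verdict, "verdict_slow": s.slow_test.verdict,
            "slow_mean": s.slow_mean, "slow_sd": s.slow_sd, "n": s.slow_n,
        })
    return pd.DataFrame(rows)


def binding_to_dict(params: BindingParameters) -> dict:
    return {"kd_uM": params.kd_ref,
            "delta_H_kcal_mol": params.delta_H,
            "T_ref_C": params.T_ref - 273.15,
            "delta_Cp_kcal_mol_K": params.delta_Cp}


def binding_from_dict(d: dict) -> BindingParameters:
    return BindingParameters(
        kd_ref=float(d["kd_uM"]),
        delta_H=float(d["delta_H_kcal_mol"]),
        T_ref=float(d["T_ref_C"]) + 273.15,
        delta_Cp=float(d.get("delta_Cp_kcal_mol_K", 0.0)))


_SCENARIO_SCALARS = [
    "k_on", "k_off", "k_slow", "amp_fast", "amp_slow", "enzyme_total",
    "replicates", "t_start", "t_end", "n_points", "noise_sd",
    "T_initial", "T_final", "f0", "trp_step_frac", "background_frac", "seed",
]


def scenario_to_dict(s: KineticScenario) -> dict:
    d = {k: getattr(s, k) for k in _SCENARIO_SCALARS}
    d["ligand_totals"] = list(s.ligand_totals)
    d["binding"] = binding_to_dict(s.binding)
    return d


def scenario_from_dict(d: dict) -> KineticScenario:
    kwargs = {k: d[k] for k in _SCENARIO_SCALARS if k in d}
    if "ligand_totals" in d:
        kwargs["ligand_totals"] = tuple(d["ligand_totals"])
    if "binding" in d:
        kwargs["binding"] = binding_from_dict(d["binding"])
    return KineticScenario(**kwargs)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-sample seeds derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(x % (2 ** 31)) for x in state]


def simulate_dataset(scenario: KineticScenario, outdir: str | Path,
                     enzyme_label: str = "enzyme") -> pd.DataFrame:
    """Write a full simulated titration to disk and return its manifest.

    Produces one CSV per transient (replicates x concentrations), a
    free-Trp reference transient, a manifest CSV, the scenario config as
    YAML, and a JSON sidecar with the ground-truth parameters of every
    sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_samples = len(scenario.ligand_totals) * scenario.replicates
    seeds = replicate_seeds(scenario.seed, n_samples + 1)
    rows, truth = [], {}
    i = 0
    for conc in scenario.ligand_totals:
        for rep in range(1, scenario.replicates + 1):
            sid = f"{enzyme_label}_L{conc:g}_r{rep}"
            rec = generate_transient(scenario, conc, seeds[i], replicate=rep,
                                     label=sid)
            fname = f"{sid}.csv"
            write_transient_csv(rec, outdir / fname)
            rows.append({"sample_id": sid, "enzyme_uM": scenario.enzyme_total,
                         "ligand_uM": conc, "replicate": rep, "file": fname})
            truth[sid] = {k: v for k, v in rec.extras.items()}
            i += 1
    ref = generate_reference_transient(scenario, seed=seeds[-1])
    write_transient_csv(ref, outdir / "reference.csv")
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, outdir / "manifest.csv")
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    (outdir / "scenario.yaml").write_text(yaml.safe_dump(scenario_to_dict(scenario)))
    return manifest
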
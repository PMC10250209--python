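"""Tabular I/O, configuration and the end-to-end pipeline driver.

Interchange formats: TSV with a header row for tables (units embedded in
the column names), single-plane TIFF for kymographs, JSON for fit
reports, YAML for configuration. Every pipeline run writes a resolved
copy of its configuration and a structured log (seeds, version, config
hash) next to its outputs so results are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding, diffusion, excision, kymo, residence, synthetic
from .errors import FitFailureError, InvalidParameterError, SchemaError

SCHEMA_VERSION = "1"

# column name -> dtype kind ("f" float, "i" int, "b" bool, "s" str)
TABLE_SCHEMAS = {
    "trajectory": {"particle_id": "s", "frame": "i", "time_s": "f",
                   "position_kb": "f", "position_um": "f"},
    "dwell": {"particle_id": "s", "duration_s": "f", "censored": "b",
              "motile": "b"},
    "isotherm": {"conc_nM": "f", "replicate": "i", "pct_bound": "f"},
    "bands": {"condition": "s", "time_min": "f", "substrate": "f",
              "product": "f", "background": "f", "replicate": "i"},
    "particles": {"particle_id": "s", "channel": "s", "position_kb": "f",
                  "first_frame": "i", "last_frame": "i", "motile": "b"},
}
OPTIONAL_COLUMNS = {"dwell": {"condition": "s"}, "trajectory": {"phase": "s"}}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against a named schema.

    Checks for missing/extra columns (a same-stem column with a
    different unit suffix is reported as a unit mismatch) and coerces
    dtypes, naming the offending row and column on failure.
    """
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    spec = dict(TABLE_SCHEMAS[schema])
    optional = OPTIONAL_COLUMNS.get(schema, {})

    missing = set(spec) - set(df.columns)
    extra = set(df.columns) - set(spec) - set(optional)
    for col in sorted(missing):
        stem = col.rsplit("_", 1)[0]
        culprit = [c for c in extra if c.rsplit("_", 1)[0] == stem]
        if culprit:
            raise SchemaError(
                f"{path.name}: column {culprit[0]!r} where {col!r} expected "
                f"(unit mismatch)")
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    if extra:
        raise SchemaError(f"{path.name}: unexpected columns {sorted(extra)}")

    spec.update({c: optional[c] for c in optional if c in df.columns})
    for col, kind in spec.items():
        if kind == "s":
            continue
        for row_idx, raw in df[col].items():
            try:
                if kind == "b":
                    df.loc[row_idx, col] = _BOOL_MAP[str(raw).strip().lower()]
                elif kind == "i":
                    df.loc[row_idx, col] = int(raw)
                else:
                    df.loc[row_idx, col] = float(raw)
            except (KeyError, ValueError, TypeError):
                raise SchemaError(
                    f"{path.name}: row {row_idx + 2}, column {col!r}: "
                    f"cannot parse {raw!r}") from None
        df[col] = df[col].astype({"b": bool, "i": int, "f": float}[kind])
    return df


def write_trajectories(trajs, path) -> None:
    rows = []
    for t in trajs:
        for i in range(len(t)):
            rows.append({"particle_id": t.particle_id, "frame": int(t.frames[i]),
                         "time_s": t.times[i], "position_kb": t.positions_kb[i],
                         "position_um": t.positions_um[i],
                         "phase": t.phase_labels[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dwells(dwells, path) -> None:
    rows = [{"particle_id": d.particle_id, "duration_s": d.duration,
             "censored": d.censored, "motile": d.motile,
             "condition": d.condition} for d in dwells]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def dwells_from_table(df: pd.DataFrame) -> list:
    return [residence.DwellRecord(
        particle_id=str(r.particle_id), duration=float(r.duration_s),
        censored=bool(r.censored), motile=bool(r.motile),
        condition=str(getattr(r, "condition", ""))) for r in df.itertuples()]


def write_isotherm(data: binding.IsothermData, path) -> None:
    rows = []
    for rep in range(data.pct_bound.shape[0]):
        for c, y in zip(data.protein_concs, data.pct_bound[rep]):
            rows.append({"conc_nM": c, "replicate": rep, "pct_bound": y})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def isotherm_from_table(df: pd.DataFrame, dna_conc: float = 8.0) -> binding.IsothermData:
    wide = df.pivot(index="replicate", columns="conc_nM", values="pct_bound")
    wide = wide.sort_index(axis=1)
    return binding.IsothermData(protein_concs=wide.columns.to_numpy(float),
                                pct_bound=wide.to_numpy(float),
                                dna_conc_total=dna_conc)


def write_kymograph_tiff(kym: kymo.KymographImage, path) -> None:
    import tifffile

    tifffile.imwrite(path, kym.pixels.astype(np.float32),
                     metadata={"pixel_size_um": kym.pixel_size,
                               "frame_interval_s": kym.frame_interval,
                               "origin_um": kym.origin_um})


def read_kymograph_tiff(path, pixel_size: float, frame_interval: float,
                        origin_um: float = 0.0) -> kymo.KymographImage:
    import tifffile

    return kymo.KymographImage(pixels=tifffile.imread(path),
                               pixel_size=pixel_size,
                               frame_interval=frame_interval,
                               origin_um=origin_um)


# ---------------------------------------------------------------------------
# pipeline

_DEFAULT_BLOCKS = {
    "seed": 0,
    "stages": ["tracking", "msd", "crtd", "coloc", "isotherm", "excision"],
    "simulate": {
        "n_trajectories": 10,
        "diff_coeff_um2_s": 0.0265,
        "alpha": 1.36,
        "duration_s": 60.0,
        "dwell_rate_per_s": 1.4e-4,
        "dwell_rate_plus_competitor_per_s": 1.195e-3,
        "n_dwells": 200,
        "kd_nM": 15.0,
        "dna_conc_nM": 8.0,
        "protein_concs_nM": [1, 2, 4, 8, 16, 32, 64, 128],
        "excision_k_per_min": 0.012,
        "excision_amplitude_pct": 60.0,
        "excision_times_min": [0, 10, 20, 40, 60, 90, 120, 180],
        "n_a": 8, "n_b": 8, "n_shared": 3,
    },
    "config": {},          # SimulationConfig overrides
    "msd": {"fit_fraction": 0.25, "min_lag": 1},
    "crtd": {"mode": "censored", "window_s": None},
    "coloc": {"max_distance_kb": 1.5, "min_overlap_frames": 10},
    "inputs": {},          # optional paths: dwells, isotherm, bands ...
    "out_dir": "tightropekit_out",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    resolved: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_BLOCKS)))
    schema_version: str = SCHEMA_VERSION

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        base = json.loads(json.dumps(_DEFAULT_BLOCKS))
        unknown = set(d) - set(base) - {"schema_version"}
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key, val in d.items():
            if key == "schema_version":
                continue
            if isinstance(base.get(key), dict):
                sub_unknown = set(val) - set(base[key])
                if sub_unknown and key != "inputs" and key != "config":
                    raise InvalidParameterError(
                        f"unknown keys in {key!r}: {sorted(sub_unknown)}")
                base[key].update(val)
            else:
                base[key] = val
        return cls(resolved=base)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        # output location is not part of the scientific configuration
        payload = {k: v for k, v in self.resolved.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path, cfg_hash):
    payload = {"config_hash": cfg_hash, "schema_version": SCHEMA_VERSION,
               "result": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict:
    """Run the requested stages in dependency order, writing all reports.

    Stages: tracking (simulate trajectories -> kymographs -> re-extract),
    msd (per-particle diffusion fits), crtd (dwell survival fits for the
    two competitor conditions and their half-life fold), coloc
    (two-color pairing), isotherm (Kd fit), excision (stimulation fold).
    Inputs listed under ``inputs:`` are read from disk instead of being
    simulated. Deterministic for a given config + seed.
    """
    r = config.resolved
    if seed is not None:
        r = dict(r, seed=int(seed))
    base_seed = int(r["seed"])
    out_dir = Path(r["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    sim = r["simulate"]
    scfg = synthetic.SimulationConfig(**r["config"])
    inputs = r["inputs"]
    for name, p in inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name!r}: {p} does not exist")

    log = {"seed": base_seed, "config_hash": cfg_hash,
           "schema_version": SCHEMA_VERSION, "stages": []}
    report: dict = {}
    trajs = []

    if "tracking" in r["stages"]:
        for i in range(int(sim["n_trajectories"])):
            traj = synthetic.simulate_trajectory(
                float(sim["diff_coeff_um2_s"]), float(sim["alpha"]), scfg,
                duration=float(sim["duration_s"]), seed=base_seed * 10007 + i,
                particle_id=f"traj{i}")
            km = synthetic.render_kymograph(traj, cfg=scfg,
                                            seed=base_seed * 20011 + i)
            ext = kymo.extract_trajectory(km, method="centroid",
                                          particle_id=f"traj{i}")
            trajs.append(kymo.segment_phases(ext))
        write_trajectories(trajs, out_dir / "trajectories.tsv")
        log["stages"].append("tracking")

    if "msd" in r["stages"]:
        if not trajs:
            raise InvalidParameterError("msd stage requires tracking stage")
        fits = []
        for traj in trajs:
            curve = diffusion.compute_msd(traj)
            fit = diffusion.fit_diffusion(curve, float(r["msd"]["fit_fraction"]),
                                          particle_id=traj.particle_id)
            try:
                fit.alpha = diffusion.fit_alpha(
                    curve, float(r["msd"]["fit_fraction"]),
                    min_lag=int(r["msd"]["min_lag"])).alpha
            except (InvalidParameterError, FitFailureError):
                pass  # stationary/degenerate phase: alpha stays None
            fits.append(fit)
        pd.DataFrame([{**asdict(f)} for f in fits]).to_csv(
            out_dir / "diffusion_fits.tsv", sep="\t", index=False)
        accepted = [f for f in fits if f.accepted]
        report["msd"] = {
            "n_fits": len(fits), "n_accepted": len(accepted),
            "mean_D_um2_s": float(np.mean([f.diff_coeff for f in accepted]))
            if accepted else None,
        }
        _write_json(report["msd"], out_dir / "msd_summary.json", cfg_hash)
        log["stages"].append("msd")

    if "crtd" in r["stages"]:
        window = r["crtd"]["window_s"] or np.inf
        if "dwells" in inputs:
            dwells_a = dwells_from_table(read_table(inputs["dwells"], "dwell"))
            conditions = {"all": dwells_a}
        else:
            conditions = {
                "alone": synthetic.simulate_dwell_times(
                    float(sim["dwell_rate_per_s"]), int(sim["n_dwells"]),
                    window=window, cfg=scfg, seed=base_seed * 30013),
                "plus_competitor": synthetic.simulate_dwell_times(
                    float(sim["dwell_rate_plus_competitor_per_s"]),
                    int(sim["n_dwells"]), window=window, cfg=scfg,
                    seed=base_seed * 30013 + 1),
            }
        crtd_fits = {}
        for name, dwells in conditions.items():
            write_dwells(dwells, out_dir / f"dwells_{name}.tsv")
            curve = residence.build_crtd(dwells, mode=r["crtd"]["mode"])
            curve.to_csv(out_dir / f"crtd_{name}.tsv", sep="\t", index=False)
            crtd_fits[name] = residence.fit_crtd(curve)
        report["crtd"] = {name: asdict(f) for name, f in crtd_fits.items()}
        if {"alone", "plus_competitor"} <= set(crtd_fits):
            report["crtd"]["half_life_fold"] = residence.half_life_fold(
                crtd_fits["alone"], crtd_fits["plus_competitor"])
        _write_json(report["crtd"], out_dir / "crtd_fits.json", cfg_hash)
        log["stages"].append("crtd")

    if "coloc" in r["stages"]:
        a, b, truth = synthetic.simulate_two_color_particles(
            int(sim["n_a"]), int(sim["n_b"]), int(sim["n_shared"]), cfg=scfg,
            seed=base_seed * 40031)
        venn = residence.pair_colocalized(
            a, b, max_distance_kb=float(r["coloc"]["max_distance_kb"]),
            min_overlap_frames=int(r["coloc"]["min_overlap_frames"]))
        report["coloc"] = {k: venn[k] for k in
                           ("a_only", "b_only", "colocalized",
                            "fraction_colocalized")}
        report["coloc"]["n_ground_truth_pairs"] = len(truth)
        _write_json(report["coloc"], out_dir / "coloc_venn.json", cfg_hash)
        log["stages"].append("coloc")

    if "isotherm" in r["stages"]:
        if "isotherm" in inputs:
            data = isotherm_from_table(read_table(inputs["isotherm"], "isotherm"),
                                       dna_conc=float(sim["dna_conc_nM"]))
        else:
            data = synthetic.simulate_isotherm(
                float(sim["kd_nM"]), float(sim["dna_conc_nM"]),
                sim["protein_concs_nM"], seed=base_seed * 50021)
            write_isotherm(data, out_dir / "isotherm.tsv")
        fit = binding.fit_kd(data)
        report["isotherm"] = {"kd_nM": fit.kd_apparent, "stderr": fit.kd_stderr,
                              "r2": fit.r_squared,
                              "constraints": fit.constraints_record}
        _write_json(report["isotherm"], out_dir / "kd_fit.json", cfg_hash)
        log["stages"].append("isotherm")

    if "excision" in r["stages"]:
        times = sim["excision_times_min"]
        k = float(sim["excision_k_per_min"])
        amp = float(sim["excision_amplitude_pct"])
        tc_minus = synthetic.simulate_excision_timecourse(
            k, amp / 4.5, times, seed=base_seed * 60013, condition="-UVDDB")
        tc_plus = synthetic.simulate_excision_timecourse(
            k, amp, times, seed=base_seed * 60013 + 1, condition="+UVDDB")
        stim = excision.stimulation_fold(tc_plus, tc_minus)
        report["excision"] = {"fold": stim.fold, "basis": stim.basis,
                              "reference_time_min": stim.reference_time}
        _write_json(report["excision"], out_dir / "excision_fold.json", cfg_hash)
        log["stages"].append("excision")

    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dict(r, schema_version=SCHEMA_VERSION), fh,
                       sort_keys=True)
    try:
        from importlib.metadata import version
        log["version"] = version("tightropekit")
    except Exception:
        log["version"] = "unknown"
    _write_json(log, out_dir / "run_log.json", cfg_hash)
    return report


__all__ = [
    "TABLE_SCHEMAS", "read_table", "write_trajectories", "write_dwells",
    "dwells_from_table", "write_isotherm", "isotherm_from_table",
    "write_kymograph_tiff", "read_kymograph_tiff", "PipelineConfig",
    "run_pipeline",
]
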
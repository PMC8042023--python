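"""End-to-end reproducible runs: simulate -> (render/detect) -> analyze ->
partitioning model, with a manifest tying outputs to the resolved
configuration and seed.

Stages communicate only through their declared files; the manifest records
the resolved configuration, the root seed and its named substream seeds,
and a checksum of every output file, so two runs with identical manifests
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from wallmark import __version__, bernoulli, kinematics, simulate
from wallmark.config import SimConfig, config_from_dict, load_config
from wallmark.rng import substream_seeds
from wallmark.tables import write_table

log = logging.getLogger("wallmark")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: SimConfig | dict | str | Path, out_dir: str | Path,
                 seed: int | None = None, n_generations: int = 1,
                 bernoulli_generations: int = 3,
                 bernoulli_particles: int = 200_000) -> dict:
    """Run the full demonstration pipeline and write a manifest.

    Simulates a founder cell through ``n_generations`` divisions, exports
    truth/observed/geometry/lineage tables, runs the kinematic analysis
    (traces, per-landmark velocities, inert-zone changepoint fit, pairwise
    expansion and its per-interval rate), evaluates the observed lineage
    against the shift map, and runs the population smoothing simulation.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, dict):
        cfg = config_from_dict(config)
    else:
        cfg = config
    if seed is not None:
        cfg.rng_seed = int(seed)
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # -- simulate ---------------------------------------------------------
    log.info("simulate: %d generation(s), seed %d", n_generations, cfg.rng_seed)
    lineage_res = simulate.simulate_generations(cfg, n_generations)
    truth, observed = simulate.add_noise_and_export(lineage_res.positions, cfg)
    written.append(write_table(truth, out / "truth.csv"))
    written.append(write_table(observed, out / "observed.csv"))
    written.append(write_table(lineage_res.frames, out / "geometry.csv"))
    written.append(write_table(lineage_res.lineage, out / "lineage.csv"))

    # -- analyze ----------------------------------------------------------
    founder = observed[observed["cell_id"] == "0"]
    traces = kinematics.traces_from_table(founder)
    fits = [kinematics.fit_VPy(tr) for tr in traces if len(tr) >= 3]
    fit_df = pd.DataFrame([asdict(f) for f in fits])
    written.append(write_table(fit_df, out / "velocities.csv"))
    iz = kinematics.fit_inert_zone(fit_df, seed=cfg.rng_seed)
    with open(out / "inert_zone.json", "w") as fh:
        json.dump({"P_yc_um": iz.P_yc, "k_per_min": iz.k, "rss": iz.rss,
                   "ci95_P_yc_um": iz.ci_Pyc, "n_motors": iz.n_motors}, fh, indent=2)
    written.append(out / "inert_zone.json")
    pairs = kinematics.pair_kinematics(traces, iz.P_yc, dt=cfg.frame_interval_dt)
    written.append(write_table(pairs, out / "pairs.csv", "pairs"))
    hubble = kinematics.hubble_series(pairs)
    written.append(write_table(hubble, out / "hubble.csv"))

    trace_rows = pd.concat(
        [pd.DataFrame({"cell_id": tr.cell_id, "motor_id": tr.motor_id,
                       "time_min": tr.time_min, "x_um": tr.x_um, "y_um": tr.y_um,
                       "P_y_um": tr.P_y_um}) for tr in traces],
        ignore_index=True,
    )
    written.append(write_table(trace_rows, out / "traces.csv", "traces"))

    samples, slopes = kinematics.normalize_positions(
        kinematics.traces_from_table(truth), lineage_res.frames, cfg.cap_size_c)
    written.append(write_table(samples, out / "normalized.csv"))
    written.append(write_table(slopes, out / "normalized_slopes.csv"))

    # -- partitioning model ----------------------------------------------
    comp = bernoulli.predict_vs_observed(lineage_res.lineage)
    with open(out / "bernoulli_fit.json", "w") as fh:
        json.dump({"fraction_on_map": comp.fraction_on_map,
                   "tolerance": comp.tolerance,
                   "max_residual": float(comp.residuals["residual"].max())}, fh, indent=2)
    written.append(out / "bernoulli_fit.json")
    evo = bernoulli.evolve_distribution(bernoulli.DistributionSim(
        n_particles=bernoulli_particles, generations=bernoulli_generations,
        rng_seed=cfg.rng_seed))
    written.append(write_table(evo.histograms, out / "bernoulli_histograms.csv"))
    with open(out / "bernoulli_ks.json", "w") as fh:
        json.dump({"ks_to_uniform": evo.ks_to_uniform}, fh, indent=2)
    written.append(out / "bernoulli_ks.json")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "root_seed": cfg.rng_seed,
        "substream_seeds": substream_seeds(cfg.rng_seed),
        "n_generations": n_generations,
        "outputs": {p.name: _sha256(p) for p in written},
        "timestamp_unix": time.time(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
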
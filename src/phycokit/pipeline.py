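"""End-to-end orchestration of the antenna analysis stages.

A run is described by a plain-text (YAML) config naming the stages to execute
and, per stage, either explicit input files or ``simulate: true`` to run on
the packaged synthetic scenario.  All randomness is seeded from one root
seed; reruns with identical config and seed produce byte-identical primary
outputs.  The config is echoed verbatim into the output directory and every
stage writes its tables plus one combined JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chromatogram as chrom
from . import em as em_mod
from . import geometry as geom
from . import sequences as seqs
from . import spectra as spectra_mod
from . import synth

log = logging.getLogger("phycokit.pipeline")

STAGES = ("sequences", "chromatogram", "spectra", "geometry", "em")

_STAGE_KEYS = {
    "sequences": {"simulate", "fasta", "braced_min", "braced_max"},
    "chromatogram": {"simulate", "pink", "purple", "peaks", "linear_region"},
    "spectra": {"simulate", "absorption", "eem", "exclusion"},
    "geometry": {"simulate", "structure", "chain", "res_id", "noise_sd", "n_cases"},
    "em": {"simulate", "image", "scale_nm_per_px", "sigma", "low", "high"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    seed: int = 0
    log_level: str = "INFO"
    options: dict = field(default_factory=dict)
    source_text: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        known_top = {"stages", "seed", "log_level"} | set(STAGES)
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages", [])
        if not stages:
            raise ValueError("config must list at least one stage")
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        options = {}
        for stage in STAGES:
            opts = raw.get(stage, {}) or {}
            extra = set(opts) - _STAGE_KEYS[stage]
            if extra:
                raise ValueError(f"unknown keys for stage {stage!r}: {sorted(extra)}")
            options[stage] = opts
        return cls(
            stages=list(stages),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            options=options,
            source_text=text,
        )


def validate_inputs(config: RunConfig) -> list[str]:
    """Check referenced inputs exist and look well-formed; never modifies data.

    Returns a list of failure messages (empty when everything validates).
    """
    failures: list[str] = []
    for stage in config.stages:
        opts = config.options.get(stage, {})
        if opts.get("simulate", not opts):
            continue
        for key in ("fasta", "pink", "purple", "peaks", "absorption", "eem",
                    "structure", "image"):
            p = opts.get(key)
            if p is not None and not Path(p).exists():
                failures.append(f"{stage}: missing input file {p}")
        if stage == "chromatogram":
            for key in ("pink", "purple"):
                p = opts.get(key)
                if p and Path(p).exists():
                    try:
                        trace = chrom.read_trace(p)
                        if 560 not in trace.channels:
                            failures.append(f"{stage}: {p} lacks a 560 nm channel")
                        if 280 not in trace.channels:
                            failures.append(
                                f"{stage}: {p} lacks the 280 nm channel needed for "
                                "saturation correction"
                            )
                    except Exception as exc:  # malformed table
                        failures.append(f"{stage}: {p}: {exc}")
        if stage == "spectra":
            p = opts.get("eem")
            if p and Path(p).exists():
                try:
                    spectra_mod.read_eem_table(p)
                except Exception as exc:
                    failures.append(f"{stage}: {p}: {exc}")
    return failures


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the requested stages in dependency order.

    Writes per-stage tables, a combined ``report.json`` and a log into
    ``out_dir``; any stage failure aborts with the failing stage named while
    partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.source_text or _render_config(config))
    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("phycokit")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    import phycokit

    log.info("phycokit %s, seed %d, stages %s", phycokit.__version__, config.seed,
             config.stages)
    report: dict = {"seed": config.seed, "stages": {}}
    try:
        for stage in sorted(config.stages, key=STAGES.index):
            log.info("stage %s starting", stage)
            runner = globals()[f"_run_{stage}"]
            report["stages"][stage] = runner(config, out)
            log.info("stage %s done", stage)
    except Exception as exc:
        report["failed_stage"] = stage
        (out / "report.json").write_text(_to_json(report))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    text = _to_json(report)
    (out / "report.json").write_text(text)
    report["report_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    return report


def _render_config(config: RunConfig) -> str:
    return yaml.safe_dump(
        {"stages": config.stages, "seed": config.seed, **config.options}
    )


def _to_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(type(o).__name__)

    return json.dumps(obj, indent=2, sort_keys=True, default=default)


# ---------------------------------------------------------------------------
# stage runners


def _run_sequences(config: RunConfig, out: Path) -> dict:
    opts = config.options.get("sequences", {})
    if opts.get("fasta"):
        candidates = seqs.read_candidates_fasta(opts["fasta"])
    else:
        candidates, _ = synth.gen_alpha_sequences(seed=config.seed)
    window = (int(opts.get("braced_min", 5)), int(opts.get("braced_max", 8)))
    catalog = seqs.build_catalog(candidates, braced_window=window)
    seqs.write_catalog(catalog, out / "alpha_catalog.tsv", out / "alpha_mature.fasta")
    counts: dict[str, int] = {}
    for s in catalog:
        counts[s.form_class] = counts.get(s.form_class, 0) + 1
    return {"n_candidates": len(candidates), "n_unique": len(catalog),
            "form_counts": counts}


def _run_chromatogram(config: RunConfig, out: Path) -> dict:
    opts = config.options.get("chromatogram", {})
    if opts.get("pink") and opts.get("purple"):
        pink = chrom.read_trace(opts["pink"], "pink")
        purple = chrom.read_trace(opts["purple"], "purple")
        named = _read_named_peaks(opts["peaks"])
        linear = opts.get("linear_region", {})
        lin_pink = tuple(linear.get("pink", (pink.volume[0], pink.volume[-1])))
        lin_purple = tuple(linear.get("purple", (purple.volume[0], purple.volume[-1])))
    else:
        sc = synth.antenna_scenario()
        pink, purple, _ = synth.gen_chromatogram(
            sc["peaks"], volume=sc["volume"],
            saturation_level=sc["saturation_level"], seed=config.seed,
        )
        named = sc["named_peaks"]
        lin_pink, lin_purple = sc["linear_region"]["pink"], sc["linear_region"]["purple"]
    pink = chrom.rescale_saturated_channel(pink, lin_pink)
    purple = chrom.rescale_saturated_channel(purple, lin_purple)
    table = chrom.spectrotype_fractions(pink, purple, named)
    table.to_tsv(out / "abundances.tsv")
    return json.loads(table.to_json())


def _read_named_peaks(path) -> list[chrom.NamedPeak]:
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    return [
        chrom.NamedPeak(
            name=str(r["name"]), fraction=str(r["fraction"]),
            window=(float(r["lo"]), float(r["hi"])),
            spectrotype=str(r.get("spectrotype", r["name"])),
        )
        for _, r in df.iterrows()
    ]


def _run_spectra(config: RunConfig, out: Path) -> dict:
    opts = config.options.get("spectra", {})
    result: dict = {}
    if opts.get("absorption"):
        spectra = spectra_mod.read_spectra_table(opts["absorption"])
        mean = spectra_mod.average_and_normalize(spectra, "unit_area")
        peaks = spectra_mod.find_peaks(mean, min_prominence=0.1)
    else:
        absorption, _ = synth.gen_absorption(
            synth.PE555_ABS_BANDS, noise_sd=0.002, seed=config.seed, label="PE555"
        )
        mean = absorption.normalized("unit_area")
        peaks = spectra_mod.find_peaks(mean, (450.0, 700.0), min_prominence=0.1)
    result["absorption_peaks"] = [
        {"wavelength_nm": w, "height": h, "uncertainty_nm": u} for w, h, u in peaks
    ]
    if opts.get("eem"):
        eem = spectra_mod.read_eem_table(opts["eem"])
        exclusion = [tuple(x) for x in opts.get("exclusion", [])]
    else:
        eem, _ = synth.gen_eem(
            synth.PE555_EEM_PEAKS, noise_sd=0.002, seed=config.seed, label="PE555"
        )
        exclusion = [(545.0, 605.0)]
    emission = spectra_mod.eem_to_emission(eem)
    corrected, ray = spectra_mod.remove_rayleigh(emission, exclusion)
    em_peaks = spectra_mod.find_peaks(corrected, min_prominence=0.1)
    spectra_mod.write_spectra_table([corrected], out / "emission_corrected.tsv")
    result["rayleigh"] = {"c": ray.c, "n": ray.n, "residual_rms": ray.residual_rms}
    result["emission_peaks"] = [
        {"wavelength_nm": w, "height": h, "uncertainty_nm": u} for w, h, u in em_peaks
    ]
    return result


def _run_geometry(config: RunConfig, out: Path) -> dict:
    opts = config.options.get("geometry", {})
    rows = []
    if opts.get("structure"):
        atoms = geom.read_structure(opts["structure"]).strip_solvent()
        chain = opts.get("chain")
        res_id = opts.get("res_id")
        bilin = geom.extract_bilin(atoms, chain, int(res_id))
        bilins = [("input", bilin)]
    else:
        bilins = []
        for i, ident in enumerate(("PEB", "PCB", "DBV")):
            b, _ = synth.gen_bilin_coords(
                ident, noise_sd=float(opts.get("noise_sd", 0.05)),
                seed=config.seed + i,
            )
            bilins.append((ident, b))
    for label, b in bilins:
        call = geom.call_chromophore_identity(b)
        pair_d = call.dihedrals["D"]
        rows.append(
            {
                "bilin": label,
                "identity": call.identity,
                "ring_a": call.ring_a_verdict,
                "cd_angle_deg": round(call.cd_bridge_angle, 2),
                "theta_inner_D": round(pair_d.theta_inner, 2),
                "theta_outer_D": round(pair_d.theta_outer, 2),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "chromophores.tsv", sep="\t", index=False)
    return {"chromophores": rows}


def _run_em(config: RunConfig, out: Path) -> dict:
    opts = config.options.get("em", {})
    if opts.get("image"):
        from skimage import io as skio

        arr = np.asarray(skio.imread(opts["image"]), dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        image = em_mod.GrayscaleImage(arr, float(opts["scale_nm_per_px"]))
    else:
        image, _ = synth.gen_striation_image(seed=config.seed)
    res = em_mod.measure_striations(
        image, sigma=float(opts.get("sigma", 2.0)),
        low=float(opts.get("low", 0.2)), high=float(opts.get("high", 0.4)),
    )
    np.savetxt(out / "striation_distances_nm.tsv", res.distances, fmt="%.4f")
    return {
        "mean_nm": res.mean, "sd_nm": res.sd,
        "dark_band_mean_nm": res.dark_mean, "bright_band_mean_nm": res.bright_mean,
        "n_distances": int(res.distances.size),
    }
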
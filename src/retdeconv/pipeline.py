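"""End-to-end orchestration: simulate -> markers -> deconvolve -> ctDEGs.

One seed drives every stage through numpy SeedSequence spawning (stream k is
``SeedSequence(seed).spawn``'s k-th child, taken modulo 2**31 where an integer
seed is required), so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate, de, deconvolve, io, markers
from .errors import ConfigError
from .synthetic import SimConfig, simulate_bulk, simulate_reference

log = logging.getLogger("retdeconv")

_KNOWN_SECTIONS = {"sim", "markers", "deconvolution", "ctdeg", "seed", "outdir", "contrast"}
_KNOWN_MARKER_KEYS = {"scope", "alpha", "min_fc", "min_pct_target", "max_pct_other"}
_KNOWN_DECONV_KEYS = {"min_pct", "min_cells", "markers_only"}
_KNOWN_CTDEG_KEYS = {"robust", "alpha", "direction"}


@dataclass
class PipelineConfig:
    """Validated, nested configuration of a synthetic end-to-end run."""

    sim: SimConfig
    seed: int = 0
    outdir: str = "retdeconv_run"
    contrast: tuple[str, str] | None = None
    markers: dict = field(default_factory=dict)
    deconvolution: dict = field(default_factory=dict)
    ctdeg: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        for section, allowed in (
            ("markers", _KNOWN_MARKER_KEYS),
            ("deconvolution", _KNOWN_DECONV_KEYS),
            ("ctdeg", _KNOWN_CTDEG_KEYS),
        ):
            bad = set(raw.get(section, {})) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) in '{section}': {sorted(bad)}")
        seed = int(raw.get("seed", 0))
        sim_kwargs = dict(raw.get("sim", {}))
        sim_kwargs.setdefault("seed", seed)
        try:
            sim = SimConfig(**sim_kwargs)
        except TypeError as exc:
            raise ConfigError(f"unknown key in 'sim': {exc}") from exc
        contrast = raw.get("contrast")
        if contrast is not None:
            contrast = tuple(contrast)
            if len(contrast) != 2:
                raise ConfigError("contrast: expected [control_label, disease_label]")
        return cls(
            sim=sim,
            seed=seed,
            outdir=str(raw.get("outdir", "retdeconv_run")),
            contrast=contrast,
            markers=dict(raw.get("markers", {})),
            deconvolution=dict(raw.get("deconvolution", {})),
            ctdeg=dict(raw.get("ctdeg", {})),
        )

    def config_hash(self) -> str:
        payload = {
            "sim": {k: v for k, v in asdict(self.sim).items() if not isinstance(v, dict)},
            "sim_props": {k: list(map(float, v)) for k, v in self.sim.proportions_by_condition.items()},
            "seed": self.seed,
            "contrast": self.contrast,
            "markers": self.markers,
            "deconvolution": self.deconvolution,
            "ctdeg": self.ctdeg,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child integer seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write stage outputs under outdir, return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    try:
        from importlib.metadata import version

        manifest["version"] = version("retdeconv")
    except Exception:  # pragma: no cover - editable metadata quirks
        manifest["version"] = "unknown"

    seeds = spawn_seeds(config.seed, 2)

    # stage 1: simulation
    sim_cfg = config.sim
    sim_cfg.seed = seeds[0]
    sc, truth = simulate_reference(sim_cfg)
    bulk = simulate_bulk(sim_cfg, truth, seed=seeds[1])
    io.write_single_cell(sc, outdir / "sc")
    io.write_bulk(bulk, outdir / "bulk")
    io.write_ground_truth(truth, outdir / "truth")
    manifest["stages"]["simulate"] = {
        "status": "completed",
        "n_genes": sc.n_genes,
        "n_cells": sc.n_cells,
        "n_samples": bulk.counts.shape[1],
    }

    # stage 2: marker selection
    try:
        mk = markers.select_markers(sc, **config.markers)
        frame = markers.markers_to_frame(mk)
        frame.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        manifest["stages"]["markers"] = {
            "status": "completed",
            "n_markers": int(len(frame)),
            "per_type": {ct: ms.m for ct, ms in mk.items()},
        }
    except Exception as exc:
        _fail(manifest, "markers", exc, outdir)
        raise

    # stage 3: deconvolution
    try:
        dk = dict(config.deconvolution)
        markers_only = dk.pop("markers_only", False)
        genes = sorted({g for ms in mk.values() for g in ms.genes}) if markers_only else None
        sig = deconvolve.build_signature(sc, genes=genes, **dk)
        props = deconvolve.estimate_proportions(bulk, sig)
        table = props.proportions.copy()
        table.insert(0, "condition", bulk.conditions.reindex(table.index))
        table["residual_norm"] = props.residual_norm
        table.rename_axis("sample_id").to_csv(outdir / "proportions.tsv", sep="\t")
        contrast = config.contrast or (bulk.conditions.iloc[0], bulk.conditions.unique()[-1])
        prop_tests = deconvolve.test_proportion_difference(
            props.proportions, bulk.conditions, contrast[0], contrast[1]
        )
        prop_tests.to_csv(outdir / "prop_tests.tsv", sep="\t")
        manifest["stages"]["deconvolve"] = {
            "status": "completed",
            "n_signature_genes": len(sig.genes),
            "contrast": list(contrast),
        }
    except Exception as exc:
        _fail(manifest, "deconvolve", exc, outdir)
        raise

    # stage 4: calibrated ctDEG detection + plain bulk DE
    try:
        contrast = config.contrast or (bulk.conditions.iloc[0], bulk.conditions.unique()[-1])
        filtered = de.filter_genes(bulk)
        de_res = de.nb_wald_test(filtered, contrast[0], contrast[1])
        de_res.rename_axis("gene").to_csv(outdir / "de_results.tsv", sep="\t")
        ct_res = calibrate.detect_ctdegs(filtered, mk, contrast[0], contrast[1], **config.ctdeg)
        ct_res.table.to_csv(outdir / "ctdegs.tsv", sep="\t", index=False)
        pc_frame = pd.DataFrame(
            [
                {"cell_type": ct, "PC": pc.PC, "m_used": pc.m_used, "estimator": pc.estimator}
                for ct, pc in ct_res.pc.items()
            ]
        )
        pc_frame.to_csv(outdir / "pc.tsv", sep="\t", index=False)
        manifest["stages"]["ctdeg"] = {
            "status": "completed",
            "n_tested": int(len(ct_res.table)),
            "n_significant": int((ct_res.table["p_adj"] < 0.05).sum()),
        }
    except Exception as exc:
        _fail(manifest, "ctdeg", exc, outdir)
        raise

    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _fail(manifest: dict, stage: str, exc: Exception, outdir: Path) -> None:
    manifest["stages"][stage] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
    io.write_json(manifest, outdir / "manifest.json")
    (outdir / "FAILED").write_text(f"{stage}: {type(exc).__name__}: {exc}\n")
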
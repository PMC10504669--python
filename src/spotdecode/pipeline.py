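"""Decode→QC orchestration over one or more fields of view.

Stages write their outputs under the run's output directory so any stage can
be re-run from the previous stage's saved files:

- ``codebook_used.json`` — the codebook after optional blank insertion
- ``<fov>.transcripts.csv`` — decoded transcript table per FOV
- ``<fov>.qc.yml`` / ``combined.qc.yml`` — QC reports
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from spotdecode import qc as qc_module
from spotdecode.core import (
    Codebook,
    SpotTable,
    insert_off_target_barcodes,
    read_transcripts,
    write_transcripts,
)
from spotdecode.decoder import DecodeConfig, decode
from spotdecode.simulate import assign_cells_grid

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    codebook_path: str
    fovs: dict[str, str]  # fov name -> spots csv path
    output_dir: str
    seed: int
    decode: DecodeConfig
    insert_off_target: int = 0
    off_target_min_distance: int = 2
    ripley: bool = True
    ripley_n_mc: int = 100
    alpha: float = 0.05
    cell_grid: tuple[int, int] | None = None
    save_intermediates: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = (
                json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
            )
        decode_cfg = DecodeConfig(**doc["decode"])
        fovs = doc["fovs"]
        if isinstance(fovs, list):
            fovs = {f["name"]: f["spots"] for f in fovs}
        missing = [p for p in [doc["codebook"], *fovs.values()] if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        cells = doc.get("cell_grid")
        return cls(
            codebook_path=doc["codebook"],
            fovs=fovs,
            output_dir=doc["output_dir"],
            seed=int(doc["seed"]),
            decode=decode_cfg,
            insert_off_target=int(doc.get("insert_off_target", 0)),
            off_target_min_distance=int(doc.get("off_target_min_distance", 2)),
            ripley=bool(doc.get("ripley", True)),
            ripley_n_mc=int(doc.get("ripley_n_mc", 100)),
            alpha=float(doc.get("alpha", 0.05)),
            cell_grid=tuple(cells) if cells else None,
            save_intermediates=bool(doc.get("save_intermediates", True)),
        )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("decode")
def run_decode_stage(config: RunConfig) -> dict[str, object]:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    codebook = Codebook.from_spacetx_json(config.codebook_path)
    if config.insert_off_target > 0:
        codebook = insert_off_target_barcodes(
            codebook,
            config.insert_off_target,
            config.off_target_min_distance,
            seed=config.seed,
        )
    codebook.to_spacetx_json(out / "codebook_used.json")
    transcripts = {}
    for fov in sorted(config.fovs):
        spots = SpotTable.read_csv(config.fovs[fov])
        table = decode(spots, codebook, config.decode)
        if config.cell_grid:
            table = assign_cells_grid(
                table, spots.fov_width, spots.fov_height, *config.cell_grid
            )
        write_transcripts(table, out / f"{fov}.transcripts.csv")
        transcripts[fov] = table
        logger.info("fov %s: %d transcripts from %d spots", fov, len(table), len(spots))
    return transcripts


@_stage("qc")
def run_qc_stage(config: RunConfig) -> qc_module.QCReport:
    out = Path(config.output_dir)
    codebook_path = out / "codebook_used.json"
    if not codebook_path.exists():
        raise FileNotFoundError(
            f"{codebook_path} not found; run the decode stage first"
        )
    codebook = Codebook.from_spacetx_json(codebook_path)
    transcripts = {
        fov: read_transcripts(out / f"{fov}.transcripts.csv")
        for fov in sorted(config.fovs)
    }
    spots = {fov: SpotTable.read_csv(path) for fov, path in config.fovs.items()}
    report = qc_module.build_report(
        transcripts,
        spots,
        codebook,
        ripley=config.ripley,
        seed=config.seed,
        n_mc=config.ripley_n_mc,
        alpha=config.alpha,
    )
    for fov, metrics in report.per_fov.items():
        qc_module.QCReport(per_fov={fov: metrics}).to_yaml(out / f"{fov}.qc.yml")
    report.to_yaml(out / "combined.qc.yml")
    return report


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ("decode", "qc")):
    """Run the requested stages in order; later stages read saved outputs."""
    results = {}
    if "decode" in stages:
        results["transcripts"] = run_decode_stage(config)
    if "qc" in stages:
        results["qc"] = run_qc_stage(config)
    return results
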
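"""End-to-end orchestration: scene -> tiles -> model -> mask -> report.

``run_pipeline`` executes the five stages (prep, train, segment, measure,
evaluate) on a synthetic scene, writes every artifact (config snapshot,
truth table, masks, checkpoint, training log, crown table, report) into an
output directory, and logs per-stage wall time and key counts.  One run
seed fans out into independent per-stage seeds so stages are individually
reproducible.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from . import crown_metrics, evaluation, io, resunet, synthetic
from .config import RunConfig
from .errors import CrownscopeError

logger = logging.getLogger(__name__)


def run_pipeline(
    config: RunConfig,
    out_dir,
    n_crowns: int = 20,
    size: int = 1024,
    write_artifacts: bool = True,
) -> evaluation.EvaluationReport:
    """Run the synthetic end-to-end pipeline; returns the evaluation report.

    Raises :class:`CrownscopeError` subclasses with the failing stage named
    in the message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if write_artifacts:
        config.to_yaml(out / "config.yaml")

    stage = "prep"
    try:
        t0 = time.perf_counter()
        scene, truth = synthetic.gen_scene(
            n_crowns=n_crowns, size=size, seed=config.stage_seed("scene")
        )
        tiles = synthetic.scene_to_tiles(
            scene, truth, config.combo, tile_size=config.tile_size,
            augment=config.augment, max_height=config.max_height,
        )
        grid, stack = synthetic.prepare_input_grid(
            scene, truth, config.combo, max_height=config.max_height
        )
        chm = stack.band("chm") if "chm" in stack.band_names else None
        logger.info("stage=prep wall=%.1fs tiles=%d layers=%d",
                    time.perf_counter() - t0, len(tiles), config.layers)
        if write_artifacts:
            truth.metrics_table.to_csv(out / "truth.csv")
            io.write_mask(out / "mask_truth.png", truth.mask,
                          resolution=truth.resolution)
            io.write_raster(out / "ortho.tif",
                            scene.pixels[:, :, :3].astype("uint8"),
                            resolution=truth.resolution)
            io.write_raster(out / "dsm.tif",
                            scene.band("dsm").astype("float32"),
                            resolution=truth.resolution)

        stage = "train"
        t0 = time.perf_counter()
        model_config = config.model_config()
        model = resunet.build_resunet(model_config)
        model, log = resunet.train(model, tiles, model_config)
        logger.info(
            "stage=train wall=%.1fs epochs=%d best_epoch=%d best_miou=%.4f",
            time.perf_counter() - t0, log.last_epoch, log.best_epoch,
            log.best_miou,
        )
        if write_artifacts:
            log.to_csv(out / "training_log.csv")
            resunet.save_checkpoint(out / "model.ckpt", model, log)

        stage = "segment"
        t0 = time.perf_counter()
        pred_mask = resunet.predict_mask(
            model, grid, threshold=config.threshold, tile_size=config.tile_size
        )
        logger.info("stage=segment wall=%.1fs", time.perf_counter() - t0)
        if write_artifacts:
            io.write_mask(out / "mask_pred.png", pred_mask,
                          resolution=truth.resolution)

        stage = "measure"
        t0 = time.perf_counter()
        instances = crown_metrics.extract_crown_instances(
            pred_mask, resolution=truth.resolution,
            min_crown_pixels=config.min_crown_pixels, chm=chm,
        )
        logger.info("stage=measure wall=%.1fs instances=%d",
                    time.perf_counter() - t0, len(instances))
        if write_artifacts:
            crown_metrics.instances_to_frame(instances).to_csv(
                out / "crowns.csv", index=False
            )

        stage = "evaluate"
        t0 = time.perf_counter()
        report = evaluation.evaluate_run(
            pred_mask, truth.to_instances(), resolution=truth.resolution,
            iou_threshold=config.iou_threshold,
            min_crown_pixels=config.min_crown_pixels, chm=chm,
        )
        logger.info(
            "stage=evaluate wall=%.1fs tp=%d fp=%d fn=%d",
            time.perf_counter() - t0, report.counts.tp, report.counts.fp,
            report.counts.fn,
        )
        if write_artifacts:
            report.to_json(out / "report.json")
        return report
    except CrownscopeError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
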
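"""End-to-end toy study: synthesize, transplant, train, inpaint, evaluate.

This chains every stage at a scale a single CPU handles in minutes:

1. generate donor phantoms (with artifacts) and artifact-free recipients;
2. transplant donor artifacts into recipients (all pairs) for paired data;
3. train the 2D artifact/heart detector on the donor phantoms;
4. train the 3D inpainting GAN on the transplant cases of all but one
   recipient;
5. run the three-arm comparison (uncorrected / solid fill / inpainted)
   on the held-out recipient's cases and write per-case + aggregate
   reports.

Everything derives from one global seed, so a rerun reproduces every
volume, weight and report byte for byte at a fixed thread count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig, derive_seeds
from .detection import ArtifactDetector
from .evaluation import detection_report, three_arm_comparison
from .inpainting import InpaintingModel
from .phantom import load_manifest, make_case, make_dataset
from .transplant import build_training_set

log = logging.getLogger(__name__)

# Study scale: donors x recipients transplant cases, one recipient held out.
N_DONORS = 4
N_RECIPIENTS = 5


def run_demo(seed: int, out_dir: str | Path, run_config: RunConfig | None = None,
             n_donors: int = N_DONORS, n_recipients: int = N_RECIPIENTS,
             detector_epochs: int = 10, inpaint_epochs: int = 30) -> dict:
    """Run the full toy study; returns the summary dict it also writes."""
    rc = run_config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(seed, 6)

    log.info("generating %d donor and %d recipient phantoms", n_donors, n_recipients)
    donor_manifest = make_dataset(
        n_donors, seeds[0], out / "phantoms" / "donors",
        spec=rc.build("phantom"), aspec=rc.build("artifact"),
    )
    recipient_manifest = make_dataset(
        n_recipients, seeds[1], out / "phantoms" / "recipients",
        spec=rc.build("phantom"), aspec=rc.build("artifact"),
    )

    log.info("transplanting artifacts (all donor x recipient pairs)")
    pair_manifest = build_training_set(
        donor_manifest, recipient_manifest, seeds[2], out / "transplants",
        margin_vox=int(rc.evaluation.get("margin_vox", 3)),
    )
    pairs = pd.read_csv(pair_manifest)
    eval_recipient = n_recipients - 1
    train_rows = pairs[(pairs.recipient != eval_recipient) & pairs.usable]
    eval_rows = pairs[(pairs.recipient == eval_recipient) & pairs.usable]
    train_cases = load_manifest(train_rows)
    eval_cases = load_manifest(eval_rows)
    log.info("%d training / %d evaluation transplant cases",
             len(train_cases), len(eval_cases))

    log.info("training the artifact detector on the donor phantoms")
    det_cfg = rc.build("detection", seed=seeds[3], epochs=detector_epochs)
    det = ArtifactDetector(load_manifest(donor_manifest), det_cfg).fit()
    det.save(out / "checkpoints" / "detector")
    held_out = make_case(seeds[3] + 500_001, rc.build("phantom"), rc.build("artifact"))
    det_pred = det.detect(held_out.corrupted)
    det_metrics = detection_report(det_pred.artifact_mask, held_out.artifact_mask)

    log.info("training the inpainting model on %d cases", len(train_cases))
    inp_cfg = rc.build("inpaint", seed=seeds[4], epochs=inpaint_epochs)
    if not rc.inpaint:  # no explicit architecture requested -> toy scale
        inp_cfg = type(inp_cfg).toy(seed=seeds[4], epochs=inpaint_epochs)
    inp = InpaintingModel(train_cases, inp_cfg).fit()
    inp.save(out / "checkpoints" / "inpainter")

    log.info("three-arm comparison on the held-out recipient")
    report = three_arm_comparison(
        eval_cases, inp,
        surface_tolerance_vox=float(rc.evaluation.get("surface_tolerance_vox", 3.0)),
        blood_pool_hu=float(rc.evaluation.get("blood_pool_hu", 200.0)),
    )
    reports = out / "reports"
    reports.mkdir(exist_ok=True)
    report.to_csv(reports / "metrics.csv")

    agg = report.aggregate()
    summary = {
        "seed": seed,
        "n_train_cases": len(train_cases),
        "n_eval_cases": len(eval_cases),
        "detection": {k: round(float(v), 6) for k, v in det_metrics.items()},
        "arms": {
            arm: {
                metric: round(float(agg.loc[arm, (metric, "mean")]), 6)
                for metric in ("surface_dice", "dice", "msd_mm", "hd_mm",
                               "hd95_mm", "masked_ssim", "masked_l1_hu")
                if (metric, "mean") in agg.columns
                and pd.notna(agg.loc[arm, (metric, "mean")])
            }
            for arm in agg.index
        },
        "inpaint_loss_history": {
            k: [round(v, 6) for v in vs] for k, vs in inp.history.items()
        },
        "detector_loss_history": [round(v, 6) for v in det.loss_history],
    }
    (reports / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    resolved = RunConfig(
        seed=seed, out=str(out), log_level=rc.log_level,
        phantom=rc.phantom, artifact=rc.artifact,
        detection=rc.detection, inpaint=rc.inpaint, evaluation=rc.evaluation,
    )
    resolved.to_yaml(out / "resolved_config.yaml")
    return summary
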
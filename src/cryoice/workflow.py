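"""End-to-end workflow pieces: configured runs, inference, filtering.

Mirrors the user-facing pipeline: preprocess a tilt-series stack, import
polygon annotations, fine-tune from a checkpoint, run inference over the full
stack, and quantify/export percent-non-vitrified statistics. The CLI in
:mod:`cryoice.cli` is a thin shell over these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .evaluation import DatasetReport, percent_nonvitrified, write_report_csv, \
    write_report_json
from .io_formats import Micrograph, SegmentationMask, TiltSeriesStack, \
    preprocess, write_mask_png
from .meta import MetaConfig
from .model import ModelParameters, forward, predict_mask

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_inference", "filter_by_percent", "pad_to_divisor"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    input_stack: str = ""
    annotation_file: str = ""
    checkpoint: str = ""
    output_dir: str = "out"
    target_long_side: int = 64
    clip_sigma: float = 3.0
    threshold: float = 0.5
    max_percent: float = 100.0
    shots: int = 5
    finetune_epochs: int = 20
    meta: MetaConfig = field(default_factory=MetaConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        meta = MetaConfig(**raw.pop("meta", {}))
        return cls(meta=meta, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def pad_to_divisor(image: np.ndarray, divisor: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad trailing edges so both sides divide `divisor`.

    Returns the padded image and the original (rows, cols) so predictions can
    be cropped back.
    """
    h, w = image.shape
    ph = (-h) % divisor
    pw = (-w) % divisor
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
    return image, (h, w)


def run_inference(params: ModelParameters, stack: TiltSeriesStack,
                  threshold: float = 0.5,
                  target_long_side: int | None = None,
                  clip_sigma: float = 3.0,
                  output_dir=None) -> tuple[DatasetReport, list[SegmentationMask]]:
    """Segment every micrograph in a stack and quantify non-vitrified area.

    Each micrograph is preprocessed (z-score, clip, rescale, optional resize),
    reflect-padded to the model's stride divisor, segmented, cropped back and
    thresholded. The per-image percentages are aggregated into a
    :class:`DatasetReport`. An empty stack yields an empty (zero-row) report.
    When output_dir is set, masks (PNG) and the report (CSV + JSON) are
    written there.
    """
    masks: list[SegmentationMask] = []
    percents: list[float] = []
    ids: list[str] = []
    d = params.config.divisor
    for mic in stack:
        m = mic
        if target_long_side is not None:
            m = preprocess(m, target_long_side=target_long_side,
                           clip_sigma=clip_sigma)
        padded, (h, w) = pad_to_divisor(m.image, d)
        with ad.no_grad():
            logits = forward(params, padded[None])
        mask = predict_mask(logits.data[0, :h, :w], threshold)
        mask.image_ref = f"{mic.source_id}#{mic.tilt_index}"
        masks.append(mask)
        percents.append(percent_nonvitrified(mask))
        ids.append(mask.image_ref)
    report = DatasetReport.from_percents(percents, image_ids=ids)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, mask in enumerate(masks):
            write_mask_png(out / f"mask_{i:04d}.png", mask)
        write_report_csv(out / "report.csv", report)
        write_report_json(out / "report.json", report)
    return report, masks


def filter_by_percent(report: DatasetReport, max_percent: float) -> list[int]:
    """Indices of images whose non-vitrified percentage is <= max_percent."""
    return [i for i, p in enumerate(report.per_image_percent) if p <= max_percent]
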
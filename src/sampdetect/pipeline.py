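"""End-to-end run configuration and the detect->track->classify->report
pipeline, streaming frame by frame.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as _classify
from . import report as _report
from .detect import DetectionWindow, DetectParams, detect_frame
from .io import FrameStack, read_frames
from .measure import DEFAULT_PIXEL_SCALE_UM
from .track import LinkParams, Tracker, count_events

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("sampdetect")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serialised into the output dir."""

    input_path: str | None = None
    output_dir: str = "sampdetect_out"
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    frame_rate_fps: float = 10.0
    window: tuple[int, int, int, int] | None = None   # x0, y0, w, h
    detect: DetectParams = field(default_factory=DetectParams)
    link: LinkParams = field(default_factory=LinkParams)
    classifier: str = "rough"          # "rough" or path to a CNN model file
    run_id: str = "run"
    frame_range: tuple[int, int] | None = None   # pump-pulsation trimming
    frame_stride: int = 1
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["detect"] = dataclasses.asdict(self.detect)
        d["link"] = dataclasses.asdict(self.link)
        d = _tuples_to_lists(d)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "detect" in d:
            d["detect"] = DetectParams(**d["detect"])
        if "link" in d:
            d["link"] = LinkParams(**d["link"])
        for k in ("window", "frame_range"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


@dataclass
class PipelineResult:
    records: list
    summary: _report.RunSummary
    counted_tracks: list
    predictions: list
    csv_path: Path
    window: DetectionWindow


def run_pipeline(config: RunConfig,
                 frames: FrameStack | np.ndarray | None = None) -> PipelineResult:
    """Run detect -> track -> measure -> classify -> report.

    Frames may be passed directly (e.g. straight from the simulator) or
    read from ``config.input_path``.  Candidates carry their 100x100 crop
    from the moment of detection, so the representative's crop is available
    when its track terminates.
    """
    if frames is None:
        if config.input_path is None:
            raise ValueError("config.input_path is required when frames are not given")
        frames = read_frames(config.input_path, config.pixel_scale_um,
                             config.frame_rate_fps)
    if isinstance(frames, np.ndarray):
        frames = FrameStack(frames, config.pixel_scale_um, config.frame_rate_fps)

    h, w = frames.frame_shape
    if config.window is not None:
        window = DetectionWindow(*config.window)
    else:
        window = DetectionWindow(0, 0, w, h)
    window.validate((h, w))

    model = None
    if config.classifier != "rough":
        path = Path(config.classifier)
        if not path.exists():
            raise FileNotFoundError(
                f"classifier model {path} not found; use classifier='rough' "
                f"for the rule-based mode")
        model = _classify.ClassifierModel.load(path)

    lo, hi = config.frame_range or (0, len(frames))
    tracker = Tracker(config.link)
    n_processed = 0
    for t in range(lo, min(hi, len(frames)), config.frame_stride):
        frame = frames.frames[t]
        candidates = detect_frame(frame, window, config.detect, t,
                                  config.pixel_scale_um)
        channel = frame if frame.ndim == 2 else frame[:, :, 1]
        for cand in candidates:
            cand.crop = _classify.extract_crop(channel, cand.centroid,
                                               cand.feret_max_px)
        tracker.step(t, candidates)
        n_processed += 1
        log.debug("frame %d: %d candidates, %d active tracks",
                  t, len(candidates), len(tracker.active))

    tracks = tracker.finalize()
    counted = count_events(tracks, window)
    log.info("%d frames, %d tracks, %d counted", n_processed, len(tracks),
             len(counted))

    predictions = []
    for tr in counted:
        rep = tr.representative
        if model is not None:
            predictions.append(_classify.classify(model, rep.crop))
        else:
            label = _classify.rough_classify(rep.stats)
            predictions.append(_classify.Prediction(label=label,
                                                    confidence_pct=100.0))

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{config.run_id}_tracks.csv", "w", encoding="utf-8") as fh:
        fh.write("track_id,n_frames,first_frame,last_frame,representative_frame\n")
        for tr in tracks:
            fh.write(f"{tr.track_id},{len(tr.candidates)},{tr.first_frame},"
                     f"{tr.last_frame},{tr.representative.frame_index}\n")
    records, summary = _report.emit_records(
        counted, predictions, config.pixel_scale_um, outdir,
        run_id=config.run_id, frames_processed=n_processed,
        frame_rate_fps=config.frame_rate_fps,
        config_snapshot=dataclasses.asdict(config.detect))
    config.to_yaml(outdir / f"{config.run_id}_config.yaml")
    return PipelineResult(records=records, summary=summary,
                          counted_tracks=counted, predictions=predictions,
                          csv_path=outdir / f"{config.run_id}_particles.csv",
                          window=window)
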
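"""Assemble counted tracks into particle records, crops and the run CSV.

Each counted particle gets one row in a cross-referenceable CSV (fixed
header ``particle_id,crop_file,size_px,size_um,size_category,class,
confidence_pct,frame,centroid_x,centroid_y``) and one 100x100 crop written
both as JPEG (the exchange format) and as a lossless PNG mirror, so that
re-runs can be compared byte for byte regardless of JPEG encoder version.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from . import measure
from .classify import Prediction
from .detect import DetectionWindow
from .track import Track

__all__ = ["ParticleRecord", "RunSummary", "emit_records", "write_records_csv",
           "overlay_video", "CSV_HEADER"]

CSV_HEADER = ("particle_id", "crop_file", "size_px", "size_um",
              "size_category", "class", "confidence_pct", "frame",
              "centroid_x", "centroid_y")


@dataclass(frozen=True)
class ParticleRecord:
    particle_id: int
    crop_file: str
    size_px: int
    size_um: float
    size_category: str
    label: str
    confidence_pct: float
    frame_counted: int
    centroid: tuple[float, float]


@dataclass
class RunSummary:
    total_count: int = 0
    count_by_class: dict = field(default_factory=dict)
    count_by_category: dict = field(default_factory=dict)  # class -> cat -> n
    frames_processed: int = 0
    particles_per_minute: float | None = None
    config_snapshot: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        assert self.total_count == sum(self.count_by_class.values())
        assert self.total_count == sum(
            n for per in self.count_by_category.values() for n in per.values())


def emit_records(counted_tracks: list[Track],
                 predictions: list[Prediction],
                 pixel_scale: float,
                 outdir: str | Path,
                 run_id: str = "run",
                 frames_processed: int = 0,
                 frame_rate_fps: float | None = None,
                 config_snapshot: dict | None = None,
                 ) -> tuple[list[ParticleRecord], RunSummary]:
    """Write crops + CSV for the counted tracks and return records/summary.

    ``predictions`` pairs one classifier output with each counted track.
    Raises before any processing if the output directory is unwritable.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    if len(predictions) != len(counted_tracks):
        raise ValueError("one prediction required per counted track")

    cropdir = outdir / "crops"
    cropdir.mkdir(exist_ok=True)
    ndigits = max(4, len(str(len(counted_tracks))))
    records: list[ParticleRecord] = []
    for pid, (tr, pred) in enumerate(zip(counted_tracks, predictions), start=1):
        rep = tr.representative
        crop_name = f"{run_id}_p{pid:0{ndigits}d}.jpg"
        if rep.crop is not None:
            img = Image.fromarray(rep.crop)
            img.save(cropdir / crop_name, quality=95)
            img.save(cropdir / (crop_name[:-4] + ".png"))
        size_px = rep.stats.size_px
        records.append(ParticleRecord(
            particle_id=pid,
            crop_file=crop_name,
            size_px=size_px,
            size_um=rep.stats.feret_max_px * pixel_scale,
            size_category=measure.size_category(size_px),
            label=pred.label,
            confidence_pct=pred.confidence_pct,
            frame_counted=rep.frame_index,
            centroid=rep.centroid,
        ))

    write_records_csv(records, outdir / f"{run_id}_particles.csv")

    summary = RunSummary(frames_processed=frames_processed,
                         config_snapshot=config_snapshot or {})
    summary.total_count = len(records)
    for rec in records:
        summary.count_by_class[rec.label] = summary.count_by_class.get(rec.label, 0) + 1
        per = summary.count_by_category.setdefault(rec.label, {})
        per[rec.size_category] = per.get(rec.size_category, 0) + 1
    if frame_rate_fps and frames_processed:
        minutes = frames_processed / frame_rate_fps / 60.0
        summary.particles_per_minute = summary.total_count / minutes if minutes else None
    summary.check_consistency()
    return records, summary


def write_records_csv(records: list[ParticleRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow([r.particle_id, r.crop_file, r.size_px,
                             f"{r.size_um:.2f}", r.size_category, r.label,
                             f"{r.confidence_pct:.1f}", r.frame_counted,
                             f"{r.centroid[0]:.2f}", f"{r.centroid[1]:.2f}"])


def read_records_csv(path: str | Path) -> list[ParticleRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(ParticleRecord(
                particle_id=int(row["particle_id"]),
                crop_file=row["crop_file"],
                size_px=int(row["size_px"]),
                size_um=float(row["size_um"]),
                size_category=row["size_category"],
                label=row["class"],
                confidence_pct=float(row["confidence_pct"]),
                frame_counted=int(row["frame"]),
                centroid=(float(row["centroid_x"]), float(row["centroid_y"])),
            ))
    return records


def overlay_video(frames: np.ndarray, counted_tracks: list[Track],
                  predictions: list[Prediction], window: DetectionWindow
                  ) -> np.ndarray:
    """Diagnostic overlay: window rectangle on every frame, grains circled
    and fibers boxed while visible, with running counters top-left."""
    if len(predictions) != len(counted_tracks):
        raise ValueError("one prediction required per counted track")
    out = np.empty(frames.shape[:3] + (3,), dtype=np.uint8)
    events = sorted(range(len(counted_tracks)),
                    key=lambda i: counted_tracks[i].last_frame)
    for t, frame in enumerate(frames):
        img = Image.fromarray(frame).convert("RGB")
        drw = ImageDraw.Draw(img)
        drw.rectangle([window.x0, window.y0, window.x0 + window.width - 1,
                       window.y0 + window.height - 1], outline=(255, 0, 0))
        counted_so_far = 0
        by_class = {"grain": 0, "fiber": 0}
        for i in events:
            tr, pred = counted_tracks[i], predictions[i]
            if tr.last_frame <= t:
                counted_so_far += 1
                by_class[pred.label] = by_class.get(pred.label, 0) + 1
            for cand in tr.candidates:
                if cand.frame_index == t:
                    cx, cy = cand.centroid
                    r = max(6.0, cand.feret_max_px / 2 + 3)
                    if pred.label == "grain":
                        drw.ellipse([cx - r, cy - r, cx + r, cy + r],
                                    outline=(0, 255, 0))
                    else:
                        drw.rectangle([cx - r, cy - r, cx + r, cy + r],
                                      outline=(0, 160, 255))
        drw.text((4, 2), f"frame {t}  total {counted_so_far}  "
                         f"grains {by_class.get('grain', 0)}  "
                         f"fibers {by_class.get('fiber', 0)}",
                 fill=(255, 255, 0))
        out[t] = np.asarray(img)
    return out
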
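"""End-to-end wiring: pose sequences -> skeleton images -> SEI datasets."""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

from seigait.datasets import SEIRecord, records_from_seis
from seigait.ingest import drop_short_segments
from seigait.pose import PoseSequence, validate_sequence
from seigait.render import RenderConfig, SkeletonImage, normalize_pose, render_skeleton
from seigait.sei import (
    SEIConfig,
    SkeletonEnergyImage,
    detect_key_frames,
    frame_difference_series,
    keyframe_sei_sequences,
    rolling_sei,
)

logger = logging.getLogger(__name__)

__all__ = [
    "render_sequence",
    "sequence_to_seis",
    "build_sei_records",
    "build_keyframe_records",
]


def render_sequence(
    seq: PoseSequence, render_config: RenderConfig | None = None
) -> list[SkeletonImage]:
    """Normalize and rasterize every retained frame of a pose sequence."""
    render_config = render_config or RenderConfig()
    out = []
    for frame in seq.frames:
        norm = normalize_pose(
            frame, render_config.target_height, render_config.canvas
        )
        si = render_skeleton(norm, render_config)
        out.append(
            SkeletonImage(si.pixels, segment_id=seq.segment_id, frame_index=frame.frame_index)
        )
    return out


def sequence_to_seis(
    seq: PoseSequence,
    render_config: RenderConfig | None = None,
    sei_config: SEIConfig | None = None,
) -> list[SkeletonEnergyImage]:
    """Rolling-kernel SEIs of one sequence (empty if it is too short)."""
    sei_config = sei_config or SEIConfig()
    if not validate_sequence(seq, sei_config.kernel):
        logger.warning(
            "segment %s: %d retained frames < kernel %d, discarded",
            seq.segment_id, len(seq.frames), sei_config.kernel,
        )
        return []
    sis = render_sequence(seq, render_config)
    return rolling_sei(sis, sei_config, label=seq.label)


def build_sei_records(
    sequences: Sequence[PoseSequence],
    render_config: RenderConfig | None = None,
    sei_config: SEIConfig | None = None,
) -> list[SEIRecord]:
    """The "normal" SEI dataset: every rolling window of every long-enough segment."""
    sei_config = sei_config or SEIConfig()
    kept = drop_short_segments(list(sequences), sei_config.kernel)
    records: list[SEIRecord] = []
    for seq in kept:
        seis = sequence_to_seis(seq, render_config, sei_config)
        records.extend(
            replace(rec, subject_id=seq.subject_id)
            for rec in records_from_seis(seis)
        )
    return records


def build_keyframe_records(
    sequences: Sequence[PoseSequence],
    video_frames: Sequence[Sequence],
    render_config: RenderConfig | None = None,
    sei_config: SEIConfig | None = None,
) -> list[SEIRecord]:
    """The reduced key-frame SEI dataset.

    ``video_frames[i]`` are the sampled grayscale frames the differencing
    runs on, aligned with the original frame indices of ``sequences[i]``
    before pose filtering; windows covering filtered-out frames produce no
    SEI.
    """
    sei_config = sei_config or SEIConfig()
    records: list[SEIRecord] = []
    for seq, frames in zip(sequences, video_frames):
        if len(frames) < 2:
            continue
        diffs = frame_difference_series(frames)
        keys = detect_key_frames(diffs, sei_config)
        render_cfg = render_config or RenderConfig()
        si_by_index = {
            f.frame_index: SkeletonImage(
                render_skeleton(
                    normalize_pose(f, render_cfg.target_height, render_cfg.canvas),
                    render_cfg,
                ).pixels,
                segment_id=seq.segment_id,
                frame_index=f.frame_index,
            )
            for f in seq.frames
        }
        seis = keyframe_sei_sequences(keys, si_by_index, sei_config, label=seq.label)
        if not seis:
            logger.warning(
                "segment %s: no key-frame window had %d surviving frames",
                seq.segment_id, sei_config.kernel,
            )
        records.extend(
            replace(rec, subject_id=seq.subject_id)
            for rec in records_from_seis(seis)
        )
    return records
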
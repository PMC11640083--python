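"""Adapter for the optional external pose model (requires `ultralytics`).

Wraps a pretrained keypoint detector as a pose backend: each frame is run
through the model and every detected person is returned with its COCO-17
joints, per-joint confidences, and bounding box, ready for the largest-
person selection and confidence filtering applied downstream.
"""

from __future__ import annotations

import numpy as np

from seigait.backends import PersonDetection
from seigait.pose import COCO_KEYPOINT_NAMES


class YoloV8Backend:
    name = "yolov8m"

    def __init__(self, weights: str = "yolov8m-pose.pt"):
        from ultralytics import YOLO

        self._model = YOLO(weights)

    @property
    def metadata(self) -> dict:
        n = sum(p.numel() for p in self._model.model.parameters())
        return {"weights": str(self._model.ckpt_path), "parameters": n}

    def estimate(self, frame: np.ndarray, frame_index: int = 0) -> list[PersonDetection]:
        results = self._model(frame, verbose=False)
        detections: list[PersonDetection] = []
        for res in results:
            if res.keypoints is None:
                continue
            xy = res.keypoints.xy.cpu().numpy()
            conf = (
                res.keypoints.conf.cpu().numpy()
                if res.keypoints.conf is not None
                else np.ones(xy.shape[:2])
            )
            boxes = (
                res.boxes.xyxy.cpu().numpy()
                if res.boxes is not None
                else [None] * len(xy)
            )
            for person_xy, person_conf, box in zip(xy, conf, boxes):
                kps = tuple(
                    (COCO_KEYPOINT_NAMES[i], float(x), float(y), float(c))
                    for i, ((x, y), c) in enumerate(zip(person_xy, person_conf))
                )
                bbox = tuple(float(v) for v in box) if box is not None else None
                detections.append(PersonDetection(kps, bbox=bbox))
        return detections
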
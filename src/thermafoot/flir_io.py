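"""Radiometric container I/O and the per-patient processing record.

Consumer radiometric cameras emit ordinary JPEGs whose application segments
carry a hidden 16-bit radiometric image plus the Planck/atmosphere
calibration tags needed to turn counts into temperature.  This module
decodes such containers (the dialect written by
:mod:`thermafoot.fixtures`), exposes the raw frame / visible image /
parameters / acquisition metadata, and maintains a JSON "patient record"
that accumulates provenance as the processing chain runs.

Payload dialects (auto-detected by magic bytes inside the APP7 segment):

* ``RAW1`` — a bare 16-bit block with an explicit byte-order flag;
* PNG — a 16-bit grayscale PNG embedded verbatim.

Both are normalised to host byte order on read.
"""

from __future__ import annotations

import json
import logging
import struct
import time
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np
from PIL import Image
from pydantic import BaseModel, Field, field_validator

from .radiometry import RadiometricParams

log = logging.getLogger(__name__)

__all__ = [
    "RadiometricFrame",
    "AcquisitionMeta",
    "PatientRecord",
    "NonRadiometricError",
    "IncompleteMetadataError",
    "read_radiometric_jpeg",
    "write_radiometric_jpeg",
    "init_record",
    "append_step",
]

_APP7 = 0xE7
_SEGMENT_ID = b"TFRAD\x00"
_SUB_RAW = 0x01
_SUB_PNG = 0x02
_SUB_META = 0x03
# Planck tags the camera must provide; everything else has a documented default.
_REQUIRED_TAGS = ("PB", "PR1", "PR2", "PO", "PF")

RECORD_SCHEMA_VERSION = 1


class NonRadiometricError(ValueError):
    """The JPEG carries no embedded radiometric payload."""


class IncompleteMetadataError(ValueError):
    """A required Planck tag is absent and has no default."""

    def __init__(self, tag: str):
        self.tag = tag
        super().__init__(f"incomplete metadata: required Planck tag {tag!r} is missing")


@dataclass
class RadiometricFrame:
    """Raw 2D detector counts with acquisition identity.

    ``counts`` are dimensionless digital units, finite and non-negative.
    """

    counts: np.ndarray
    timestamp: float = 0.0
    camera_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 2D array")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and >= 0")

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]


class AcquisitionMeta(BaseModel):
    """Bedside acquisition conditions recorded with every scan."""

    distance_m: float = Field(0.5, gt=0, description="camera-to-object distance, m")
    air_temp_C: float = Field(22.0, description="ambient air temperature, degC")
    rel_humidity: float = Field(0.5, ge=0.0, le=1.0, description="RH fraction")
    label: str = ""
    datetime: str = ""


class ProvenanceStep(BaseModel):
    name: str
    parameters: dict = Field(default_factory=dict)
    timestamp: float = 0.0


class PatientRecord(BaseModel):
    """JSON-serialisable processing record, enriched step by step."""

    schema_version: int = RECORD_SCHEMA_VERSION
    meta: AcquisitionMeta
    params: dict = Field(default_factory=dict)
    provenance: list[ProvenanceStep] = Field(default_factory=list)
    artifacts: dict[str, str] = Field(default_factory=dict)
    # open key-value escrow for camera tags with no mapped field
    extra_tags: dict = Field(default_factory=dict)

    @field_validator("artifacts")
    @classmethod
    def _unique_paths(cls, v: dict[str, str]) -> dict[str, str]:
        paths = list(v.values())
        if len(set(paths)) != len(paths):
            raise ValueError("artifact paths must be unique")
        return v

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path) -> "PatientRecord":
        return cls.model_validate_json(Path(path).read_text())


def init_record(meta: AcquisitionMeta, params: RadiometricParams) -> PatientRecord:
    """Create a fresh record with validated metadata and empty provenance."""
    return PatientRecord(meta=meta, params=params.to_dict())


def append_step(record: PatientRecord, name: str, parameters: dict | None = None,
                timestamp: float | None = None) -> PatientRecord:
    """Return a copy of ``record`` with one more provenance entry (append-only)."""
    step = ProvenanceStep(name=name, parameters=parameters or {},
                          timestamp=time.time() if timestamp is None else timestamp)
    new = record.model_copy(deep=True)
    new.provenance.append(step)
    return new


# ---------------------------------------------------------------------------
# JPEG segment plumbing


def _iter_jpeg_segments(data: bytes):
    """Yield (marker, payload, start, end) for each marker segment before SOS."""
    if data[:2] != b"\xff\xd8":
        raise ValueError("not a JPEG file (missing SOI)")
    i = 2
    n = len(data)
    while i + 4 <= n:
        if data[i] != 0xFF:
            raise ValueError(f"corrupt JPEG segment structure at offset {i}")
        marker = data[i + 1]
        if marker == 0xD9:  # EOI
            return
        if marker == 0xDA:  # SOS: entropy-coded data follows; stop scanning
            return
        (length,) = struct.unpack(">H", data[i + 2:i + 4])
        yield marker, data[i + 4:i + 2 + length], i, i + 2 + length
        i += 2 + length


def _encode_raw_payload(counts_u16: np.ndarray, byte_order: str) -> bytes:
    h, w = counts_u16.shape
    arr = counts_u16.astype("<u2" if byte_order == "<" else ">u2")
    return (b"RAW1" + struct.pack(">HH", w, h) + byte_order.encode()
            + arr.tobytes())


def _decode_raw_payload(buf: bytes) -> np.ndarray:
    w, h = struct.unpack(">HH", buf[4:8])
    byte_order = chr(buf[8])
    arr = np.frombuffer(buf[9:9 + 2 * w * h], dtype=byte_order + "u2")
    return arr.reshape(h, w).astype(np.uint16)


def _encode_png_payload(counts_u16: np.ndarray) -> bytes:
    im = Image.fromarray(counts_u16.astype(np.uint16), mode="I;16")
    bio = BytesIO()
    im.save(bio, format="PNG")
    return bio.getvalue()


def _decode_png_payload(buf: bytes) -> np.ndarray:
    im = Image.open(BytesIO(buf))
    return np.asarray(im, dtype=np.uint16)


def _make_app7(subtype: int, body: bytes) -> bytes:
    payload = _SEGMENT_ID + bytes([subtype]) + body
    if len(payload) + 2 > 0xFFFF:
        raise ValueError("radiometric payload exceeds a single APP segment")
    return bytes([0xFF, _APP7]) + struct.pack(">H", len(payload) + 2) + payload


def write_radiometric_jpeg(path, counts: np.ndarray, visible: np.ndarray,
                           params: RadiometricParams, meta: AcquisitionMeta,
                           dialect: str = "raw", byte_swapped: bool = False,
                           quality: int = 95) -> None:
    """Write a radiometric JPEG container.

    ``counts`` must be integral in [0, 65535] (16-bit payload); ``visible``
    is an 8-bit gray or RGB array encoded as the carrier JPEG.  ``dialect``
    selects the raw-block or PNG-embedded payload; ``byte_swapped`` stores
    the raw block big-endian to exercise byte-order normalisation.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0) or np.any(counts > 0xFFFF) or \
            not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be integral in [0, 65535] for the 16-bit payload")
    c16 = np.round(counts).astype(np.uint16)

    vis = np.asarray(visible)
    if vis.dtype != np.uint8:
        vis = np.clip(vis, 0, 255).astype(np.uint8)
    bio = BytesIO()
    Image.fromarray(vis).save(bio, format="JPEG", quality=quality)
    carrier = bio.getvalue()

    if dialect == "raw":
        seg_counts = _make_app7(_SUB_RAW,
                                _encode_raw_payload(c16, ">" if byte_swapped else "<"))
    elif dialect == "png":
        seg_counts = _make_app7(_SUB_PNG, _encode_png_payload(c16))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    meta_body = json.dumps({"params": params.to_dict(),
                            "meta": meta.model_dump()}).encode()
    seg_meta = _make_app7(_SUB_META, meta_body)

    out = carrier[:2] + seg_counts + seg_meta + carrier[2:]
    Path(path).write_bytes(out)


def read_radiometric_jpeg(path):
    """Decode a radiometric JPEG.

    Returns ``(frame, visible, params, meta)``.  Raises
    :class:`NonRadiometricError` if no payload is embedded and
    :class:`IncompleteMetadataError` when a required Planck tag is absent.
    The input file is never modified.
    """
    data = Path(path).read_bytes()
    counts = None
    tags: dict | None = None
    for marker, payload, _s, _e in _iter_jpeg_segments(data):
        if marker != _APP7 or not payload.startswith(_SEGMENT_ID):
            continue
        subtype = payload[len(_SEGMENT_ID)]
        body = payload[len(_SEGMENT_ID) + 1:]
        if subtype in (_SUB_RAW, _SUB_PNG):
            # auto-detect the dialect from the payload's own magic bytes
            if body[:4] == b"RAW1":
                counts = _decode_raw_payload(body)
            elif body[:4] == b"\x89PNG":
                counts = _decode_png_payload(body)
            else:
                raise NonRadiometricError(
                    "unrecognised radiometric payload magic bytes")
        elif subtype == _SUB_META:
            tags = json.loads(body.decode())
    if counts is None:
        raise NonRadiometricError(f"{path}: non-radiometric image (no embedded payload)")

    tags = tags or {}
    ptags = dict(tags.get("params", {}))
    for tag in _REQUIRED_TAGS:
        if tag not in ptags:
            raise IncompleteMetadataError(tag)
    params = RadiometricParams.from_dict(ptags)
    meta = AcquisitionMeta(**tags.get("meta", {}))
    if "Tw_K" not in ptags or "Tr_K" not in ptags:
        log.info("Tw/Tr metadata missing; defaulting to ambient Ta = %.2f K",
                 params.Ta_K)

    frame = RadiometricFrame(counts=counts.astype(np.float64),
                             camera_id=str(params.extra.get("camera_id", "")))
    with Image.open(BytesIO(data)) as im:
        visible = np.asarray(im.convert("RGB"))
    return frame, visible, params, meta
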
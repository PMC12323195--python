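"""Dataset I/O and multi-annotator consensus masks.

The open NSR dataset layout is a directory of per-participant skin
photographs taken at five time points after patch removal, a parallel
directory of binary flushing masks, optionally a directory of arm-label
masks, and an ``info.csv`` table with the participant group and the manual
4-point flushing scores per niacin concentration.

File naming is driven by a declarative :class:`LayoutConfig` (a filename
regex with named groups) because deposited datasets differ in conventions;
the default matches what :func:`write_dataset` / the synthetic generator
emit: ``<participant>_t<minutes>.png``.

Ground-truth flushing masks are built by per-pixel majority voting over
independent annotators: a pixel belongs to the flushing area iff at least
``min_votes`` annotators (default 2) marked it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: The four methyl-nicotinate concentrations applied through the patch holes,
#: in mol/L, ordered from strongest to most dilute.
CONCENTRATIONS_M: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)

#: Minutes after patch removal at which photographs are assessed.
TIME_POINTS_MIN: tuple[int, ...] = (1, 5, 10, 15, 20)

#: Participant groups: healthy controls, depression, bipolar disorder,
#: schizophrenia.
GROUPS: tuple[str, ...] = ("HC", "DP", "BP", "SZ")

_SCORE_COLUMNS = tuple(f"score_{c}M" for c in ("0.1", "0.01", "0.001", "0.0001"))
INFO_COLUMNS = ("participant_id", "group", "time_min") + _SCORE_COLUMNS


@dataclass(frozen=True)
class Participant:
    """A study participant with a diagnostic group label."""

    id: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class NsrImage:
    """An RGB photograph of the test area with acquisition metadata."""

    pixels: np.ndarray  # H x W x 3 uint8
    participant_id: str
    time_min: int
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {self.pixels.shape}")
        if self.time_min not in TIME_POINTS_MIN:
            raise ValueError(
                f"time_min={self.time_min} not one of the assessment marks {TIME_POINTS_MIN}"
            )

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A boolean pixel mask aligned with an :class:`NsrImage`.

    ``kind`` records what the mask delineates: the flushing area, the arm
    label, the label's white reference patch, or a niacin application site.
    """

    pixels: np.ndarray  # H x W bool
    kind: str = "flush"

    _KINDS = ("flush", "label", "white_ref", "site")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected HxW mask, got shape {self.pixels.shape}")
        if self.pixels.dtype != bool:
            raise ValueError(f"mask must be boolean, got dtype {self.pixels.dtype}")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class InfoRecord:
    """One row of ``info.csv``: manual 4-point scores for one photograph."""

    participant_id: str
    group: str
    time_min: int
    manual_scores: Mapping[float, int]  # concentration (M) -> score in {0..3}

    def __post_init__(self) -> None:
        for conc, score in self.manual_scores.items():
            if conc not in CONCENTRATIONS_M:
                raise ValueError(f"unknown concentration {conc} M")
            if score not in (0, 1, 2, 3):
                raise ValueError(f"manual score {score} outside the 4-point scale")


@dataclass
class LayoutConfig:
    """Declarative description of the on-disk dataset layout.

    ``filename_pattern`` is a regex with named groups ``participant`` and
    ``time`` applied to image file names (without directory).
    """

    images_dir: str = "images"
    masks_dir: str = "masks"
    label_masks_dir: str | None = "label_masks"
    info_file: str = "info.csv"
    filename_pattern: str = r"(?P<participant>[A-Za-z0-9\-]+)_t(?P<time>\d+)\.(?:png|jpe?g)$"

    def parse_name(self, name: str) -> tuple[str, int] | None:
        m = re.match(self.filename_pattern, name)
        if m is None:
            return None
        return m.group("participant"), int(m.group("time"))

    def image_name(self, participant_id: str, time_min: int) -> str:
        return f"{participant_id}_t{time_min}.png"


def read_mask(path: str | Path, kind: str = "flush") -> BinaryMask:
    """Read a single-channel mask image; any nonzero pixel counts as true."""
    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask(pixels=arr > 0, kind=kind)


def read_image(path: str | Path, participant_id: str, time_min: int) -> NsrImage:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return NsrImage(pixels=arr, participant_id=participant_id, time_min=time_min,
                    source_path=str(path))


def _parse_info(info_path: Path) -> list[InfoRecord]:
    df = pd.read_csv(info_path, dtype={"participant_id": str})
    missing = set(INFO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{info_path}: missing columns {sorted(missing)}")
    records: list[InfoRecord] = []
    for i, row in df.iterrows():
        try:
            scores = {
                conc: int(row[col]) for conc, col in zip(CONCENTRATIONS_M, _SCORE_COLUMNS)
            }
            records.append(
                InfoRecord(
                    participant_id=str(row["participant_id"]),
                    group=str(row["group"]),
                    time_min=int(row["time_min"]),
                    manual_scores=scores,
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: one for the header line, one for 0-based indexing
            raise ValueError(f"{info_path}: unparseable row {i + 2}: {exc}") from exc
    return records


def read_dataset(
    root_path: str | Path, layout: LayoutConfig | None = None
) -> tuple[list[NsrImage], list[BinaryMask], list[InfoRecord]]:
    """Read every image with its paired flushing mask, plus the info table.

    The i-th mask corresponds to the i-th image.  A missing mask for an
    existing image is a hard error naming the file.  An empty or absent
    directory yields empty lists.
    """
    layout = layout or LayoutConfig()
    root = Path(root_path)
    if not root.exists():
        raise FileNotFoundError(f"dataset root {root} does not exist")

    images: list[NsrImage] = []
    masks: list[BinaryMask] = []
    images_dir = root / layout.images_dir
    masks_dir = root / layout.masks_dir
    if images_dir.is_dir():
        for path in sorted(images_dir.iterdir()):
            parsed = layout.parse_name(path.name)
            if parsed is None:
                continue
            pid, time_min = parsed
            mask_path = masks_dir / layout.image_name(pid, time_min)
            if not mask_path.exists():
                raise FileNotFoundError(
                    f"image {path.name} has no flushing mask at {mask_path}"
                )
            images.append(read_image(path, pid, time_min))
            masks.append(read_mask(mask_path, kind="flush"))

    info_path = root / layout.info_file
    records = _parse_info(info_path) if info_path.exists() else []
    return images, masks, records


def read_label_masks(
    root_path: str | Path, images: Sequence[NsrImage], layout: LayoutConfig | None = None
) -> list[BinaryMask]:
    """Read the arm-label masks paired with ``images`` (calibration input)."""
    layout = layout or LayoutConfig()
    if layout.label_masks_dir is None:
        raise ValueError("layout has no label_masks_dir")
    label_dir = Path(root_path) / layout.label_masks_dir
    out = []
    for img in images:
        path = label_dir / layout.image_name(img.participant_id, img.time_min)
        if not path.exists():
            raise FileNotFoundError(f"no label mask for {img.participant_id} t{img.time_min}")
        out.append(read_mask(path, kind="label"))
    return out


def consensus_mask(annotator_masks: Sequence[BinaryMask], min_votes: int = 2) -> BinaryMask:
    """Per-pixel vote: true iff at least ``min_votes`` annotators marked it.

    With ``min_votes=1`` this is the union of the annotations, with
    ``min_votes == len(annotator_masks)`` the intersection.  The default of
    2 is the consensus rule used to define the dataset's ground truth.
    """
    if len(annotator_masks) == 0:
        raise ValueError("need at least one annotator mask")
    if not 1 <= min_votes <= len(annotator_masks):
        raise ValueError(f"min_votes={min_votes} outside [1, {len(annotator_masks)}]")
    shape = annotator_masks[0].pixels.shape
    for m in annotator_masks[1:]:
        if m.pixels.shape != shape:
            raise ValueError(f"annotator mask shapes differ: {m.pixels.shape} vs {shape}")
    votes = np.zeros(shape, dtype=np.int32)
    for m in annotator_masks:
        votes += m.pixels
    return BinaryMask(pixels=votes >= min_votes, kind=annotator_masks[0].kind)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit single-channel PNG (0 background, 255 foreground)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L").save(path)


def write_masks(masks: Mapping[str, BinaryMask] | Iterable[tuple[str, BinaryMask]],
                out_path: str | Path) -> list[Path]:
    """Write named masks under ``out_path``; round-trips bit-exactly."""
    items = masks.items() if isinstance(masks, Mapping) else masks
    written = []
    for name, mask in items:
        p = Path(out_path) / name
        write_mask(mask, p)
        written.append(p)
    return written


def write_image(image: NsrImage, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels.astype(np.uint8), mode="RGB").save(path)


def write_info(records: Sequence[InfoRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "group": r.group,
            "time_min": r.time_min,
        }
        for conc, col in zip(CONCENTRATIONS_M, _SCORE_COLUMNS):
            row[col] = r.manual_scores[conc]
        rows.append(row)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=list(INFO_COLUMNS)).to_csv(path, index=False)


def write_dataset(
    images: Sequence[NsrImage],
    flush_masks: Sequence[BinaryMask],
    records: Sequence[InfoRecord],
    root_path: str | Path,
    label_masks: Sequence[BinaryMask] | None = None,
    layout: LayoutConfig | None = None,
) -> None:
    """Write a full dataset in the default on-disk layout (PNG + info.csv)."""
    layout = layout or LayoutConfig()
    root = Path(root_path)
    if len(images) != len(flush_masks):
        raise ValueError("images and flush_masks must pair up")
    for img, mask in zip(images, flush_masks):
        name = layout.image_name(img.participant_id, img.time_min)
        write_image(img, root / layout.images_dir / name)
        write_mask(mask, root / layout.masks_dir / name)
    if label_masks is not None:
        if layout.label_masks_dir is None:
            raise ValueError("layout has no label_masks_dir")
        for img, mask in zip(images, label_masks):
            name = layout.image_name(img.participant_id, img.time_min)
            write_mask(mask, root / layout.label_masks_dir / name)
    write_info(records, root / layout.info_file)
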
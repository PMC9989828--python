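"""Segmentation, tracking and contact detection of lipid droplets.

The recipe is a standard bright-blob-on-dark pipeline: Gaussian smoothing,
Otsu (or fixed) threshold, hole filling, 26-connectivity labelling and an
optional distance-transform watershed that keeps touching droplets apart —
essential during transfer, when the shrinking donor stays tangent to its
acceptor until its volume vanishes. All distances and volumes are computed
in µm with the anisotropic voxel sizes; masks stay in voxel space.

Tracking is greedy nearest-centroid linking with a displacement gate. When
two tracks contend for one detection the larger-volume track continues and
the other is terminated with a merge record — the raw material of transfer
event detection. Two droplets are "in contact" in a frame when their masks,
each dilated by one voxel, share at least one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .stack import TimelapseStack

__all__ = [
    "SegmentationConfig",
    "LinkConfig",
    "segment_frame",
    "segment_stack",
    "link_tracks",
    "detect_contacts",
]

DETECTION_COLUMNS = [
    "frame", "label", "z_vox", "y_vox", "x_vox",
    "z_um", "y_um", "x_um", "volume_um3", "equivalent_diameter_um",
]


@dataclass
class SegmentationConfig:
    """Parameters of per-frame 3D segmentation.

    ``smoothing_sigma_xy`` is in xy voxels; the z sigma is scaled by the
    voxel anisotropy so the blur is physically isotropic. ``threshold``
    is ``"otsu"`` or a fixed intensity. ``min_volume_um3`` removes
    sub-resolution specks. ``split_touching`` enables the watershed;
    ``marker_radius_um`` sets the minimum separation of watershed seeds.
    """

    smoothing_sigma_xy: float = 1.0
    threshold: str | float = "otsu"
    min_volume_um3: float = 0.05
    fill_holes: bool = True
    split_touching: bool = True
    marker_radius_um: float = 0.25
    blank_contrast_sigma: float = 6.0


@dataclass
class LinkConfig:
    """Parameters of frame-to-frame linking."""

    max_displacement_um: float = 1.0
    max_gap: int = 0


def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def segment_frame(
    frame: np.ndarray,
    voxel_size_zyx: tuple[float, float, float],
    config: SegmentationConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment one 3D frame into droplet detections.

    Returns the per-detection table (centroids in voxel and µm
    coordinates, volume in µm³, equivalent diameter) and the label image.
    A blank frame — no voxel standing out of the noise floor — yields an
    empty table rather than an error.
    """
    if frame.ndim != 3:
        raise ValueError(f"expected a 3D frame, got ndim={frame.ndim}")
    config = config or SegmentationConfig()
    vz, vy, vx = voxel_size_zyx

    sig_xy = config.smoothing_sigma_xy
    sigma = (sig_xy * vx / vz, sig_xy, sig_xy)
    smoothed = ndi.gaussian_filter(np.asarray(frame, dtype=float), sigma)

    empty = pd.DataFrame(columns=DETECTION_COLUMNS), np.zeros(frame.shape, dtype=np.int32)
    if smoothed.max() == smoothed.min():
        return empty

    # blank guard: Otsu on a pure-noise frame would split the noise itself
    noise = _robust_sigma(smoothed)
    if smoothed.max() - np.median(smoothed) < config.blank_contrast_sigma * max(noise, 1e-12):
        return empty

    if config.threshold == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        thr = float(config.threshold)
    mask = smoothed > thr
    if config.fill_holes:
        mask = ndi.binary_fill_holes(mask)

    labels = sk_label(mask, connectivity=3)

    if config.split_touching and labels.max() > 0:
        edt = ndi.distance_transform_edt(mask, sampling=voxel_size_zyx)
        fp = tuple(2 * int(np.ceil(config.marker_radius_um / v)) + 1 for v in voxel_size_zyx)
        peaks = peak_local_max(
            edt, footprint=np.ones(fp), labels=labels, exclude_border=False
        )
        peak_mask = np.zeros(mask.shape, dtype=bool)
        peak_mask[tuple(peaks.T)] = True
        # adjacent plateau peaks collapse into one seed
        markers, n_markers = ndi.label(ndi.binary_dilation(peak_mask))
        if n_markers > labels.max():
            labels = watershed(-edt, markers, mask=mask)

    voxel_volume = vz * vy * vx
    rows = []
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        volume = prop.num_pixels * voxel_volume
        if volume < config.min_volume_um3:
            continue
        cz, cy, cx = prop.centroid  # voxel coordinates
        relabel[prop.label] = next_id
        rows.append(
            {
                "frame": -1,
                "label": next_id,
                "z_vox": cz, "y_vox": cy, "x_vox": cx,
                "z_um": cz * vz, "y_um": cy * vy, "x_um": cx * vx,
                "volume_um3": volume,
                "equivalent_diameter_um": 2.0 * (3.0 * volume / (4.0 * np.pi)) ** (1 / 3),
            }
        )
        next_id += 1
    labels = relabel[labels]
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS), labels


def segment_stack(
    stack: TimelapseStack, config: SegmentationConfig | None = None
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Segment every frame; returns the detection table and label images."""
    tables, label_images = [], []
    for fi in range(stack.n_frames):
        det, lab = segment_frame(stack.frame(fi), stack.voxel_size_zyx, config)
        det = det.assign(frame=fi, time_s=stack.timestamps[fi])
        tables.append(det)
        label_images.append(lab)
    detections = pd.concat(tables, ignore_index=True)
    return detections, label_images


def link_tracks(
    detections: pd.DataFrame, config: LinkConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Link detections into tracks by greedy nearest-centroid matching.

    Candidate links are gated at ``max_displacement_um`` and consumed in
    order of increasing distance (ties: smaller volume difference), which
    makes the result independent of detection order within a frame. A
    track unmatched for more than ``max_gap`` frames dies. When a track's
    only surviving candidates are detections claimed by other tracks, the
    larger-volume track keeps the detection and the smaller one terminates
    with a merge record (``merged_into``, ``merge_frame``) — the signature
    of a donor vanishing into its acceptor.

    Returns
    -------
    tracks
        The detection table with a ``track_id`` column.
    summary
        One row per track: birth/death frames, detection count,
        ``merged_into`` (NaN if none) and ``merge_frame``.
    """
    config = config or LinkConfig()
    if detections.empty:
        cols = list(detections.columns) + ["track_id"]
        return (
            pd.DataFrame(columns=cols),
            pd.DataFrame(columns=["track_id", "birth_frame", "death_frame",
                                  "n_detections", "merged_into", "merge_frame"]),
        )

    detections = detections.sort_values(["frame", "label"]).reset_index(drop=True)
    track_id_col = np.full(len(detections), -1, dtype=int)

    active: dict[int, dict] = {}  # track_id -> state
    merges: dict[int, tuple[int, int]] = {}
    births: dict[int, int] = {}
    deaths: dict[int, int] = {}
    counts: dict[int, int] = {}
    next_track = 0

    for frame, group in detections.groupby("frame", sort=True):
        idx = group.index.to_numpy()
        pos = group[["z_um", "y_um", "x_um"]].to_numpy()
        vol = group["volume_um3"].to_numpy()
        radius = group["equivalent_diameter_um"].to_numpy() / 2.0
        tids = sorted(active)
        assigned_det: dict[int, int] = {}  # det row position -> track
        assigned_trk: set[int] = set()

        if tids and len(idx):
            tpos = np.array([active[t]["pos"] for t in tids])
            tvol = np.array([active[t]["vol"] for t in tids])
            dist = np.linalg.norm(tpos[:, None, :] - pos[None, :, :], axis=2)
            cands = [
                (dist[i, j], abs(tvol[i] - vol[j]), tids[i], j)
                for i in range(len(tids))
                for j in range(len(idx))
                if dist[i, j] <= config.max_displacement_um
            ]
            for d, dv, t, j in sorted(cands):
                if t in assigned_trk or j in assigned_det:
                    continue
                assigned_det[j] = t
                assigned_trk.add(t)
            # merge resolution: larger-volume track keeps a contested detection
            for d, dv, t, j in sorted(cands):
                if t in assigned_trk:
                    continue
                holder = assigned_det.get(j)
                if holder is not None and active[t]["vol"] > active[holder]["vol"]:
                    assigned_det[j] = t
                    assigned_trk.add(t)
                    assigned_trk.discard(holder)

        for j, t in assigned_det.items():
            row = idx[j]
            track_id_col[row] = t
            active[t].update(pos=pos[j], vol=vol[j], last_frame=frame, misses=0)
            counts[t] += 1

        # unmatched tracks: merge if their neighbourhood detection was claimed
        for t in list(active):
            if t in assigned_trk or frame <= active[t]["last_frame"]:
                continue
            merged_into = None
            if len(idx):
                d = np.linalg.norm(np.asarray(active[t]["pos"]) - pos, axis=1)
                # a vanished track merging into a neighbour: its last position
                # falls inside (or within the gate of) a claimed detection,
                # whose centroid sits an object radius away
                gate = config.max_displacement_um + radius
                candidates = [
                    j for j in np.argsort(d)
                    if d[j] <= gate[j] and j in assigned_det
                ]
                if candidates:
                    merged_into = assigned_det[candidates[0]]
            if merged_into is not None:
                merges[t] = (merged_into, frame)
                deaths[t] = active[t]["last_frame"]
                del active[t]
            else:
                active[t]["misses"] += 1
                if active[t]["misses"] > config.max_gap:
                    deaths[t] = active[t]["last_frame"]
                    del active[t]

        for j in range(len(idx)):
            if j not in assigned_det:
                t = next_track
                next_track += 1
                track_id_col[idx[j]] = t
                active[t] = {"pos": pos[j], "vol": vol[j], "last_frame": frame, "misses": 0}
                births[t] = frame
                counts[t] = 1

    for t, st in active.items():
        deaths[t] = st["last_frame"]

    tracks = detections.assign(track_id=track_id_col)
    summary = pd.DataFrame(
        [
            {
                "track_id": t,
                "birth_frame": births[t],
                "death_frame": deaths[t],
                "n_detections": counts[t],
                "merged_into": merges.get(t, (np.nan, np.nan))[0],
                "merge_frame": merges.get(t, (np.nan, np.nan))[1],
            }
            for t in sorted(births)
        ]
    )
    return tracks, summary


def detect_contacts(
    tracks: pd.DataFrame,
    label_images: list[np.ndarray],
    *,
    dilation_voxels: int = 1,
) -> pd.DataFrame:
    """Flag per-frame contacts between droplet pairs.

    Two droplets are in contact when their voxel masks, each dilated by
    ``dilation_voxels`` (1 by default; 0 reproduces the strict
    shared-voxel reading), overlap in at least one voxel. Output is
    symmetric in the pair and covers all co-alive pairs.
    """
    rows = []
    struct = np.ones((3, 3, 3), dtype=bool)
    for frame, group in tracks.groupby("frame", sort=True):
        labels = label_images[int(frame)]
        slices = ndi.find_objects(labels)
        present = group[["track_id", "label"]].to_numpy()
        masks = {}
        boxes = {}
        for tid, lab in present:
            sl = slices[int(lab) - 1]
            if sl is None:
                continue
            grown = tuple(
                slice(max(s.start - dilation_voxels - 1, 0),
                      min(s.stop + dilation_voxels + 1, dim))
                for s, dim in zip(sl, labels.shape)
            )
            m = labels[grown] == lab
            if dilation_voxels:
                m = ndi.binary_dilation(m, structure=struct, iterations=dilation_voxels)
            masks[int(tid)] = m
            boxes[int(tid)] = grown
        tids = sorted(masks)
        for i, ta in enumerate(tids):
            for tb in tids[i + 1 :]:
                ba, bb = boxes[ta], boxes[tb]
                inter = tuple(
                    slice(max(a.start, b.start), min(a.stop, b.stop))
                    for a, b in zip(ba, bb)
                )
                if any(s.stop <= s.start for s in inter):
                    touching = False
                else:
                    sub_a = masks[ta][tuple(
                        slice(s.start - a.start, s.stop - a.start)
                        for s, a in zip(inter, ba)
                    )]
                    sub_b = masks[tb][tuple(
                        slice(s.start - b.start, s.stop - b.start)
                        for s, b in zip(inter, bb)
                    )]
                    touching = bool(np.any(sub_a & sub_b))
                rows.append(
                    {"frame": int(frame), "track_a": ta, "track_b": tb,
                     "in_contact": touching}
                )
    return pd.DataFrame(rows, columns=["frame", "track_a", "track_b", "in_contact"])
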
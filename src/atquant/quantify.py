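"""Imaging readouts: density, burden, colocalization, synaptic pairing.

Conventions follow the array-tomography literature: an object in channel A
is *colocalized* with channel B when at least 25% of A's own 3D volume
overlaps B's foreground (boundary inclusive); a pre- and a post-synaptic
object form a *synaptic pair* when their physical centroids are at most
0.5 um apart (inclusive), matched one-to-one greedily by ascending
distance; *burden* is the percentage of the analysed volume occupied by
stain; *density* is objects per mm^3 of analysed (post-crop) volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .segmentation import Object3D, SegmentedStack


@dataclass(frozen=True)
class PairingCriteria:
    """The study's fixed decision thresholds, overridable only explicitly.

    ``overlap_fraction_min`` and ``pairing_distance_max`` are inclusive
    ("at least 25%", "<= 0.5 um"); ``fold_increase`` is strict (">2-fold",
    consumed by :mod:`atquant.effects`).  Keeping all three in one config
    lets boundary behaviour be asserted in one place.
    """

    overlap_fraction_min: float = 0.25
    pairing_distance_max: float = 0.5  # um
    fold_increase: float = 2.0

    def to_dict(self) -> dict:
        return {
            "overlap_fraction_min": self.overlap_fraction_min,
            "pairing_distance_max": self.pairing_distance_max,
            "fold_increase": self.fold_increase,
        }


@dataclass
class QuantResult:
    """Per-ROI quantification: one value per (channel / pair, metric)."""

    case_id: str
    treatment: str
    roi_index: int
    analysed_volume_um3: float
    object_count: dict[str, int] = field(default_factory=dict)
    density_per_mm3: dict[str, float] = field(default_factory=dict)
    burden_pct: dict[str, float] = field(default_factory=dict)
    burden_area_pct: dict[str, float] = field(default_factory=dict)
    coloc_pct: dict[tuple[str, str], float] = field(default_factory=dict)
    pair_count: int = 0
    pair_density_per_mm3: float = 0.0
    pct_pre_with_ab: float = math.nan
    pct_post_with_ab: float = math.nan
    criteria: PairingCriteria = field(default_factory=PairingCriteria)

    def to_rows(self) -> list[dict]:
        """Tidy rows (deterministic order) for CSV export."""
        base = {"case_id": self.case_id, "treatment": self.treatment, "roi_index": self.roi_index}
        rows = [dict(base, subject="roi", metric="analysed_volume_um3", value=self.analysed_volume_um3)]
        for ch in sorted(self.object_count):
            rows.append(dict(base, subject=ch, metric="object_count", value=self.object_count[ch]))
            rows.append(dict(base, subject=ch, metric="density_per_mm3", value=self.density_per_mm3[ch]))
            rows.append(dict(base, subject=ch, metric="burden_pct", value=self.burden_pct[ch]))
            if ch in self.burden_area_pct:
                rows.append(dict(base, subject=ch, metric="burden_area_pct", value=self.burden_area_pct[ch]))
        for (a, b) in sorted(self.coloc_pct):
            rows.append(dict(base, subject=f"{a}->{b}", metric="coloc_pct", value=self.coloc_pct[(a, b)]))
        rows.append(dict(base, subject="pre-post", metric="pair_count", value=self.pair_count))
        rows.append(dict(base, subject="pre-post", metric="pair_density_per_mm3", value=self.pair_density_per_mm3))
        rows.append(dict(base, subject="pre", metric="pct_with_ab", value=self.pct_pre_with_ab))
        rows.append(dict(base, subject="post", metric="pct_with_ab", value=self.pct_post_with_ab))
        return rows


def compute_burden(seg: SegmentedStack) -> float:
    """Staining burden: % of the analysed 3D volume occupied by foreground."""
    total = seg.mask.size
    if total == 0:
        raise ValueError("cannot compute burden of a zero-volume field")
    return 100.0 * seg.n_foreground / total


def compute_section_area_burden(seg: SegmentedStack) -> float:
    """Mean per-section area burden (% of section area that is foreground).

    For a full stack this equals the volume burden; it is exposed
    separately because 2D immunofluorescence readouts report % area.
    """
    if seg.mask.size == 0:
        raise ValueError("cannot compute burden of a zero-volume field")
    return float(np.mean([100.0 * m.mean() for m in seg.mask]))


def compute_density(objects: list[Object3D], analysed_volume_um3: float) -> float:
    """Object density in objects per mm^3 (1 mm^3 = 1e9 um^3)."""
    if analysed_volume_um3 <= 0:
        raise ValueError("analysed volume must be positive")
    return len(objects) / analysed_volume_um3 * 1e9


def overlap_fraction(obj: Object3D, mask_b: SegmentedStack) -> float:
    """Fraction of an object's own voxels lying in channel B's foreground."""
    flat_b = mask_b.mask.reshape(-1)
    return float(flat_b[obj.voxel_index].sum()) / obj.n_voxels


def colocalize(
    objects_a: list[Object3D],
    mask_b: SegmentedStack,
    criteria: PairingCriteria = PairingCriteria(),
) -> tuple[np.ndarray, float]:
    """Flag each A-object colocalized with channel B; return flags and %.

    Object ``a`` is colocalized iff
    ``|voxels(a) & foreground(B)| / |voxels(a)| >= overlap_fraction_min``
    (inclusive).  The denominator is the tested object's own volume, so
    colocalize(A, B) need not equal colocalize(B, A).
    """
    if not objects_a:
        raise ValueError("colocalize requires at least one object in channel A")
    for obj in objects_a:
        if obj.voxel_index.max(initial=-1) >= mask_b.mask.size:
            raise ValueError("object voxel indices fall outside mask B; geometry/field mismatch")
    flags = np.array(
        [overlap_fraction(obj, mask_b) >= criteria.overlap_fraction_min for obj in objects_a],
        dtype=bool,
    )
    return flags, 100.0 * flags.mean()


def pair_synapses(
    pre_objects: list[Object3D],
    post_objects: list[Object3D],
    criteria: PairingCriteria = PairingCriteria(),
) -> list[tuple[int, int, float]]:
    """One-to-one greedy pre/post matching by ascending centroid distance.

    Candidates are all (pre, post) with Euclidean centroid distance
    <= ``pairing_distance_max`` (inclusive, physical um).  Greedy selection
    by distance with lexicographic (pre id, post id) tie-break is
    deterministic and near-optimal at biological densities; each object
    joins at most one pair.  Returns (pre_id, post_id, distance) tuples.
    """
    if not pre_objects or not post_objects:
        return []
    pre_c = np.array([o.centroid_um for o in pre_objects])
    post_c = np.array([o.centroid_um for o in post_objects])
    d = np.sqrt(((pre_c[:, None, :] - post_c[None, :, :]) ** 2).sum(axis=2))
    ii, jj = np.nonzero(d <= criteria.pairing_distance_max)
    order = sorted(
        range(ii.size),
        key=lambda k: (d[ii[k], jj[k]], pre_objects[ii[k]].object_id, post_objects[jj[k]].object_id),
    )
    used_pre: set[int] = set()
    used_post: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        pairs.append((pre_objects[i].object_id, post_objects[j].object_id, float(d[i, j])))
    return pairs


def percent_synapses_with_ab(
    synapse_objects: list[Object3D],
    ab_mask: SegmentedStack,
    criteria: PairingCriteria = PairingCriteria(),
) -> float:
    """% of synaptic objects containing A-beta (>= 25% own-volume overlap).

    Undefined (raises) for an empty object list: reporting 0% would
    conflate "no synapses" with "no colocalization".
    """
    if not synapse_objects:
        raise ValueError("percentage undefined for an empty synapse object list")
    _, pct = colocalize(synapse_objects, ab_mask, criteria)
    return pct


def average_region_burden(burdens: list[float]) -> float:
    """Arithmetic mean of regional burdens (e.g. layers I/II, III/IV, V/VI, WM)."""
    if not burdens:
        raise ValueError("cannot average an empty list of regional burdens")
    return float(np.mean(burdens))


def quantify_roi(
    segs: dict[str, SegmentedStack],
    objects: dict[str, list[Object3D]],
    *,
    case_id: str = "",
    treatment: str = "other",
    roi_index: int = 0,
    pre_channel: str = "SYP",
    post_channel: str = "PSD95",
    ab_channel: str = "OC",
    criteria: PairingCriteria = PairingCriteria(),
) -> QuantResult:
    """Assemble the full per-ROI readout from segmented channels.

    Computes per-channel count/density/burden, % colocalization for every
    ordered channel pair, one-to-one synaptic pairing between the pre and
    post channels, and the % of pre-/post-synapses containing A-beta.
    Percentages over an empty object list are reported as NaN.
    """
    any_seg = next(iter(segs.values()))
    volume_um3 = any_seg.mask.size * any_seg.geometry.voxel_volume_um3
    res = QuantResult(case_id=case_id, treatment=treatment, roi_index=roi_index,
                      analysed_volume_um3=volume_um3, criteria=criteria)
    for ch, seg in segs.items():
        res.object_count[ch] = len(objects[ch])
        res.density_per_mm3[ch] = compute_density(objects[ch], volume_um3)
        res.burden_pct[ch] = compute_burden(seg)
        res.burden_area_pct[ch] = compute_section_area_burden(seg)
    for a in segs:
        for b in segs:
            if a == b:
                continue
            if objects[a]:
                _, pct = colocalize(objects[a], segs[b], criteria)
            else:
                pct = math.nan
            res.coloc_pct[(a, b)] = pct
    if pre_channel in segs and post_channel in segs:
        pairs = pair_synapses(objects[pre_channel], objects[post_channel], criteria)
        res.pair_count = len(pairs)
        res.pair_density_per_mm3 = len(pairs) / volume_um3 * 1e9
    if ab_channel in segs:
        if pre_channel in segs and objects[pre_channel]:
            res.pct_pre_with_ab = percent_synapses_with_ab(objects[pre_channel], segs[ab_channel], criteria)
        if post_channel in segs and objects[post_channel]:
            res.pct_post_with_ab = percent_synapses_with_ab(objects[post_channel], segs[ab_channel], criteria)
    return res
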
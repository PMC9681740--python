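"""Synthetic wound datasets with controllable, known class signal per modality.

The generator emulates the *structure* of a clinical wound-ROI dataset —
class-conditional image appearance and class-conditional location
distributions — without any claim of photorealism:

* wound classes render a class-coloured, class-textured ellipse on a
  skin-toned noisy background; normal skin (N) renders plain skin with no
  ellipse; background (BG) renders a non-skin texture;
* each wound class owns a disjoint block of body-map codes; N draws from
  the union of the wound blocks (mirroring the location overlap between
  normal skin and wounds seen in clinical data); BG always carries the
  sentinel code -1.

Signal strengths are categorical mixtures, which keeps the per-modality
Bayes-optimal accuracy exactly enumerable:

* with probability ``s_img`` an image renders its own class signature,
  otherwise a uniformly random class signature;
* a location is drawn from the class's own distribution with probability
  ``s_loc``, otherwise uniformly over all positive codes (BG excepted).

With ``location_overlap = 0`` every wound class owns a disjoint block of
codes and both modalities have Bayes accuracy ``s + (1 - s) / K`` for K
classes: 1/K at s=0, 1.0 at s=1. With ``location_overlap > 0`` part of each
wound class's location mass sits on boundary codes shared with the next
wound class, so the location evidence is graded — core codes are nearly
certain, boundary codes are two-way ambiguous. Graded evidence is what
makes fusing the two modalities strictly better than either alone: two
plain categorical votes can never beat the more reliable vote, but a vote
plus graded evidence can resolve each other's characteristic errors.
:func:`bayes_reference` enumerates all three ceilings exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .bodymap import BACKGROUND_CODE, BodyMapRegistry, MergeMap, encode_locations
from .pipeline import DatasetManifest, WoundClass, WoundRecord, write_manifest

__all__ = [
    "BayesReference",
    "SynthConfig",
    "bayes_reference",
    "generate_arrays",
    "generate_bodymap_fixture",
    "generate_dataset",
]

# distinct hue + stripe-frequency signature per class
_PALETTE: dict[WoundClass, tuple[tuple[int, int, int], int]] = {
    WoundClass.D: ((150, 40, 30), 2),  # dark red
    WoundClass.V: ((60, 60, 170), 3),  # blue
    WoundClass.AV: ((120, 40, 160), 3),  # purple
    WoundClass.P: ((220, 130, 30), 5),  # orange
    WoundClass.S: ((200, 200, 60), 7),  # yellow
}
_SKIN = np.array([224, 172, 140], dtype=np.float32)


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults are the package's test-scale conditions.

    ``s_img``/``s_loc`` in [0, 1] are the per-modality signal strengths
    (0 = no class information, 1 = fully separable). The default strengths
    make the image modality the more informative one, as observed on
    clinical wound data.
    """

    classes: tuple[WoundClass, ...] = (
        WoundClass.BG,
        WoundClass.N,
        WoundClass.D,
        WoundClass.P,
        WoundClass.S,
        WoundClass.V,
    )
    n_per_class: int = 60
    image_size: int = 64
    s_img: float = 0.8
    s_loc: float = 0.6
    locations_per_class: int = 2
    location_overlap: float = 0.5
    location_dists: dict[WoundClass, dict[int, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        classes = tuple(
            WoundClass.parse(c) if not isinstance(c, WoundClass) else c for c in self.classes
        )
        object.__setattr__(self, "classes", classes)
        if len(classes) != len(set(classes)):
            raise ValueError("duplicate classes in SynthConfig")
        if not classes:
            raise ValueError("empty class list")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not (0.0 <= self.s_img <= 1.0 and 0.0 <= self.s_loc <= 1.0):
            raise ValueError("signal strengths must lie in [0, 1]")
        if not 0.0 <= self.location_overlap <= 1.0:
            raise ValueError("location_overlap must lie in [0, 1]")
        if len(self.wound_classes) < 2 and self.location_overlap > 0 and self.location_dists is None:
            object.__setattr__(self, "location_overlap", 0.0)
        if self.location_dists is not None:
            for cls, dist in self.location_dists.items():
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"location distribution for {cls} sums to {total}")

    @property
    def wound_classes(self) -> tuple[WoundClass, ...]:
        return tuple(c for c in self.classes if c not in (WoundClass.BG, WoundClass.N))

    def _code_layout(self) -> tuple[list[int], list[int]]:
        """(core codes, boundary codes) implied by the default layout."""
        kw = max(1, len(self.wound_classes))
        core = [101 + i for i in range(kw * self.locations_per_class)]
        n_boundary = len(self.wound_classes) if len(self.wound_classes) > 1 else 0
        boundary = [201 + i for i in range(n_boundary)]
        return core, boundary

    def registry(self) -> BodyMapRegistry:
        """The (tiny) body-map registry implied by the location setup."""
        if self.location_dists is not None:
            codes = sorted(
                {c for dist in self.location_dists.values() for c in dist if c > 0}
            )
        else:
            core, boundary = self._code_layout()
            codes = core + boundary
        return BodyMapRegistry(
            {c: (f"Synthetic location {c}", "synthetic") for c in codes},
            version=f"synthetic-{len(codes)}",
        )

    def class_location_dists(self) -> dict[WoundClass, dict[int, float]]:
        """Class-conditional *signal* distributions (before uniform mixing).

        Each wound class puts ``1 - location_overlap`` of its mass uniformly
        on its own core codes and splits ``location_overlap`` over the
        boundary codes it shares with the neighbouring wound classes
        (cyclic order). N is uniform over the union of wound supports;
        BG is a point mass on -1. Overlap 0 recovers disjoint blocks.
        """
        if self.location_dists is not None:
            return self.location_dists
        core, boundary = self._code_layout()
        dists: dict[WoundClass, dict[int, float]] = {}
        wound = self.wound_classes
        kw = len(wound)
        beta = self.location_overlap if boundary else 0.0
        for i, cls in enumerate(wound):
            block = core[i * self.locations_per_class : (i + 1) * self.locations_per_class]
            d = {c: (1.0 - beta) / len(block) for c in block}
            if beta > 0:
                # boundary[i] is shared by wound classes i and i+1 (mod kw)
                d[boundary[i]] = d.get(boundary[i], 0.0) + beta / 2.0
                d[boundary[(i - 1) % kw]] = d.get(boundary[(i - 1) % kw], 0.0) + beta / 2.0
            dists[cls] = d
        union = sorted({c for cls in wound for c in dists[cls] if dists[cls][c] > 0})
        if WoundClass.N in self.classes:
            all_codes = core + boundary
            dists[WoundClass.N] = (
                {c: 1.0 / len(union) for c in union}
                if union
                else {all_codes[0]: 1.0}
            )
        if WoundClass.BG in self.classes:
            dists[WoundClass.BG] = {BACKGROUND_CODE: 1.0}
        return dists

    def mixed_location_dists(self) -> dict[WoundClass, dict[int, float]]:
        """Actual sampling distributions: signal mixed with uniform at 1 - s_loc."""
        registry = self.registry()
        codes = registry.codes
        u = 1.0 / len(codes)
        mixed: dict[WoundClass, dict[int, float]] = {}
        for cls, dist in self.class_location_dists().items():
            if cls == WoundClass.BG:
                mixed[cls] = {BACKGROUND_CODE: 1.0}
                continue
            m = {c: (1.0 - self.s_loc) * u for c in codes}
            for c, p in dist.items():
                m[c] = m.get(c, 0.0) + self.s_loc * p
            mixed[cls] = m
        return mixed


def _render(sig: WoundClass, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one uint8 RGB image carrying the signature of class ``sig``."""
    noise = rng.normal(0.0, 8.0, size=(size, size, 3)).astype(np.float32)
    if sig == WoundClass.BG:
        # non-skin: coarse green-grey checker
        yy, xx = np.mgrid[0:size, 0:size]
        checker = (((yy // 8) + (xx // 8)) % 2).astype(np.float32)
        base = np.empty((size, size, 3), dtype=np.float32)
        base[..., 0] = 90 + 40 * checker
        base[..., 1] = 110 + 50 * checker
        base[..., 2] = 90 + 30 * checker
        img = base + noise
    else:
        img = np.broadcast_to(_SKIN, (size, size, 3)).astype(np.float32) + noise
        if sig != WoundClass.N:
            color, freq = _PALETTE[sig]
            cy = size / 2 + rng.uniform(-size * 0.05, size * 0.05)
            cx = size / 2 + rng.uniform(-size * 0.05, size * 0.05)
            ry = size * rng.uniform(0.22, 0.3)
            rx = size * rng.uniform(0.22, 0.3)
            yy, xx = np.mgrid[0:size, 0:size]
            mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            stripes = 0.8 + 0.2 * np.sin(2 * np.pi * freq * (yy + xx) / size)
            wound = np.array(color, dtype=np.float32) * stripes[..., None]
            img = np.where(mask[..., None], wound + noise, img)
    return np.clip(img, 0, 255).astype(np.uint8)


def _sample(config: SynthConfig, rng: np.random.Generator):
    """Draw (class, signature class, location code) for every record."""
    classes = config.classes
    k = len(classes)
    mixed = config.mixed_location_dists()
    rows = []
    for cls in classes:
        dist = mixed[cls]
        codes = np.array(list(dist))
        probs = np.array(list(dist.values()))
        probs = probs / probs.sum()
        for _ in range(config.n_per_class):
            if rng.random() < config.s_img:
                sig = cls
            else:
                sig = classes[rng.integers(k)]
            loc = int(rng.choice(codes, p=probs))
            rows.append((cls, sig, loc))
    return rows


def generate_arrays(config: SynthConfig) -> dict:
    """In-memory dataset: images, one-hot locations, labels — index-aligned.

    Returns a dict with ``images`` (n, S, S, 3) float32 in [0, 1],
    ``location_codes`` (n,), ``locations`` one-hot (n, L+1), ``labels``
    (n,) ints under ``label_map`` (sorted class order), and the registry.
    """
    rng = np.random.default_rng(config.seed)
    registry = config.registry()
    rows = _sample(config, rng)
    ordered = sorted(set(config.classes), key=lambda c: c.value)
    label_map = {c: i for i, c in enumerate(ordered)}
    images = np.stack(
        [_render(sig, config.image_size, rng) for _, sig, _ in rows]
    ).astype(np.float32) / 255.0
    codes = np.array([loc for _, _, loc in rows], dtype=int)
    return {
        "images": images,
        "location_codes": codes,
        "locations": encode_locations(codes, registry),
        "labels": np.array([label_map[cls] for cls, _, _ in rows], dtype=int),
        "classes": [cls for cls, _, _ in rows],
        "label_map": label_map,
        "registry": registry,
    }


def generate_dataset(
    config: SynthConfig, out_dir: str | Path
) -> tuple[DatasetManifest, BodyMapRegistry]:
    """Materialize a dataset on disk: ``images/*.png`` + ``manifest.csv`` +
    ``bodymap.csv``. Deterministic under the config seed."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    registry = config.registry()
    rows = _sample(config, rng)
    records = []
    for idx, (cls, sig, loc) in enumerate(rows):
        arr = _render(sig, config.image_size, rng)
        rel = f"images/roi_{idx:05d}.png"
        Image.fromarray(arr).save(out_dir / rel)
        records.append(
            WoundRecord(
                index=idx,
                source_index=idx,
                image_path=rel,
                wound_class=cls,
                location=loc,
            )
        )
    manifest = DatasetManifest(
        name="synthetic",
        records=records,
        registry_version=registry.version,
        root=out_dir,
    )
    write_manifest(manifest, out_dir / "manifest.csv")
    registry.to_csv(out_dir / "bodymap.csv")
    return manifest, registry


@dataclass(frozen=True)
class BayesReference:
    """Exact Bayes-optimal accuracies under the generator: each modality
    alone and both modalities combined (observables independent given the
    class). The joint value is the ceiling a fused classifier can reach."""

    image_accuracy: float
    location_accuracy: float
    joint_accuracy: float


def bayes_reference(config: SynthConfig) -> BayesReference:
    """Enumerate the Bayes-optimal accuracies by exhaustive summation.

    Both modalities emit a discrete observable (the rendered signature
    identity; the location code), so each optimum is an exact sum of
    ``max_c P(x | c) / K`` over the observable's (joint) support.
    """
    classes = config.classes
    k = len(classes)

    # image: P(sig = j | class = c) = s_img * [j == c] + (1 - s_img) / k
    img_lik = np.full((k, k), (1.0 - config.s_img) / k)
    img_lik[np.diag_indices(k)] += config.s_img
    img_acc = float(img_lik.max(axis=0).sum() / k)

    mixed = config.mixed_location_dists()
    support = sorted({code for dist in mixed.values() for code in dist})
    loc_lik = np.array(
        [[mixed[cls].get(code, 0.0) for code in support] for cls in classes]
    )
    loc_acc = float(loc_lik.max(axis=0).sum() / k)

    joint_lik = np.einsum("cj,cx->cjx", img_lik, loc_lik).reshape(k, -1)
    joint_acc = float(joint_lik.max(axis=0).sum() / k)
    return BayesReference(
        image_accuracy=img_acc, location_accuracy=loc_acc, joint_accuracy=joint_acc
    )


def generate_bodymap_fixture(
    n_codes: int,
    merge_groups,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[BodyMapRegistry, MergeMap]:
    """Build a registry of ``n_codes`` codes plus a merge map from groups.

    ``merge_groups`` is either a list of explicit code groups (each merged
    onto its smallest member) or a list of group *sizes*, in which case
    member codes are drawn deterministically under ``seed``. Groups must be
    disjoint. With ``out_dir``, ``bodymap.csv`` and ``bodymap_merge.csv``
    are written there.
    """
    if n_codes < 1:
        raise ValueError("n_codes must be >= 1")
    codes = list(range(1, n_codes + 1))
    registry = BodyMapRegistry(
        {c: (f"Fixture location {c}", "fixture") for c in codes},
        version=f"fixture-{n_codes}",
    )
    groups: list[list[int]]
    if all(isinstance(g, (int, np.integer)) for g in merge_groups):
        rng = np.random.default_rng(seed)
        pool = list(rng.permutation(codes))
        groups = []
        for size in merge_groups:
            if size < 2:
                raise ValueError(f"merge group size must be >= 2: {size}")
            if size > len(pool):
                raise ValueError("not enough codes for the requested merge groups")
            groups.append(sorted(pool[:size]))
            pool = pool[size:]
    else:
        groups = [sorted(int(c) for c in g) for g in merge_groups]
    seen: set[int] = set()
    mapping: dict[int, int] = {}
    for group in groups:
        overlap = seen & set(group)
        if overlap:
            raise ValueError(f"merge groups overlap on codes {sorted(overlap)}")
        seen |= set(group)
        for code in group:
            if code not in registry:
                raise ValueError(f"merge group references unknown code {code}")
            mapping[code] = group[0]
    merge = MergeMap(mapping)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        registry.to_csv(out_dir / "bodymap.csv")
        merge.to_csv(out_dir / "bodymap_merge.csv")
    return registry, merge
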
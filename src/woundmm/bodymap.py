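"""Anatomical body-map location registry, merge simplification, one-hot codes.

Every wound ROI is tagged with a positive integer code drawn from an
enumerated registry of anatomical locations (the "body map"). The packaged
original registry holds 484 locations; a clinician-approved merge map folds
groups of neighbouring locations onto a canonical member, removing 161 codes
and leaving a simplified registry of 323. Background ROIs — crops that show
no body part at all — carry the sentinel code ``-1``.

The one-hot index space of a registry is its ascending-code order plus one
trailing slot reserved for the background sentinel, so an L-code registry
encodes into vectors of length L + 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

BACKGROUND_CODE = -1

__all__ = [
    "BACKGROUND_CODE",
    "BodyMapError",
    "BodyMapRegistry",
    "MergeMap",
    "apply_merge",
    "decode_location",
    "encode_location",
    "load_merge_map",
    "load_registry",
    "packaged_merge_path",
    "packaged_registry_path",
    "validate_registry",
]


class BodyMapError(ValueError):
    """Malformed registry, merge map, or location encoding."""


@dataclass(frozen=True)
class BodyMapRegistry:
    """Ordered set of location codes; ascending code order fixes one-hot rank."""

    entries: dict[int, tuple[str, str]]  # code -> (label, region_group)
    version: str = "custom"

    def __post_init__(self) -> None:
        ordered = dict(sorted(self.entries.items()))
        object.__setattr__(self, "entries", ordered)
        for code, (label, _group) in ordered.items():
            if code <= 0:
                raise BodyMapError(f"registry codes must be positive: {code}")
            if not str(label).strip():
                raise BodyMapError(f"empty label for code {code}")

    @property
    def codes(self) -> list[int]:
        return list(self.entries)

    @property
    def encoding_length(self) -> int:
        """One-hot vector length: one slot per code plus the background slot."""
        return len(self.entries) + 1

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: int) -> bool:
        return int(code) in self.entries

    def index_of(self, code: int) -> int:
        """Ascending-order one-hot index of ``code`` (-1 maps to the last slot)."""
        code = int(code)
        if code == BACKGROUND_CODE:
            return len(self.entries)
        try:
            return self.codes.index(code)
        except ValueError:
            raise BodyMapError(f"code {code} not in registry {self.version!r}") from None

    def label(self, code: int) -> str:
        if int(code) == BACKGROUND_CODE:
            return "background"
        return self.entries[int(code)][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, l, g) for c, (l, g) in self.entries.items()],
            columns=["code", "label", "region_group"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "entries": [
                {"code": c, "label": l, "region_group": g}
                for c, (l, g) in self.entries.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class MergeMap:
    """code -> canonical code projection over one registry's code set."""

    mapping: dict[int, int] = field(default_factory=dict)

    def canonical(self, code: int) -> int:
        """Translate an original code to its canonical (merged) code."""
        code = int(code)
        if code == BACKGROUND_CODE:
            return BACKGROUND_CODE
        return self.mapping.get(code, code)

    def __call__(self, code: int) -> int:
        return self.canonical(code)

    @property
    def n_removed(self) -> int:
        return sum(1 for k, v in self.mapping.items() if k != v)

    def to_csv(self, path: str | Path) -> None:
        rows = sorted(self.mapping.items())
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "canonical"])
            w.writerows(rows)


def load_registry(path: str | Path, version: str | None = None) -> BodyMapRegistry:
    """Read a ``code,label,region_group`` CSV into a registry.

    Raises :class:`BodyMapError` on duplicate or non-integer codes and empty
    labels; row order in the file is irrelevant (codes are sorted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"label": str, "region_group": str})
    required = {"code", "label"}
    if not required.issubset(df.columns):
        raise BodyMapError(f"registry file needs columns {sorted(required)}: {path}")
    if "region_group" not in df.columns:
        df["region_group"] = "unspecified"
    codes_raw = df["code"]
    codes_num = pd.to_numeric(codes_raw, errors="coerce")
    if codes_num.isna().any() or (codes_num != codes_num.round()).any():
        bad = codes_raw[codes_num.isna() | (codes_num != codes_num.round())]
        raise BodyMapError(f"non-integer location code(s): {bad.tolist()[:5]}")
    codes = codes_num.astype(int)
    dupes = codes[codes.duplicated()].tolist()
    if dupes:
        raise BodyMapError(f"duplicate location code(s): {sorted(set(dupes))}")
    if df["label"].isna().any() or (df["label"].str.strip() == "").any():
        raise BodyMapError("registry contains empty labels")
    entries = {
        int(c): (str(l), str(g))
        for c, l, g in zip(codes, df["label"], df["region_group"].fillna("unspecified"))
    }
    return BodyMapRegistry(entries, version=version or path.stem)


def load_merge_map(path: str | Path, registry: BodyMapRegistry | None = None) -> MergeMap:
    """Read a ``code,canonical`` CSV; optionally validate against a registry."""
    df = pd.read_csv(Path(path))
    if not {"code", "canonical"}.issubset(df.columns):
        raise BodyMapError(f"merge map needs columns ['canonical', 'code']: {path}")
    mapping = {int(c): int(t) for c, t in zip(df["code"], df["canonical"])}
    merge = MergeMap(mapping)
    _check_merge(merge, registry)
    return merge


def _check_merge(merge: MergeMap, registry: BodyMapRegistry | None) -> None:
    for code, target in merge.mapping.items():
        if registry is not None and code not in registry:
            raise BodyMapError(f"merge references code {code} absent from registry")
        if registry is not None and target not in registry:
            raise BodyMapError(f"merge canonical {target} absent from registry")
        if merge.mapping.get(target, target) != target:
            raise BodyMapError(f"canonical code {target} is not self-mapped")


def apply_merge(registry: BodyMapRegistry, merge: MergeMap) -> BodyMapRegistry:
    """Collapse merged codes, keeping the canonical member of each group.

    Returns the simplified registry; use ``merge.canonical`` to translate any
    original code into the simplified code space.
    """
    _check_merge(merge, registry)
    kept: dict[int, tuple[str, str]] = {}
    for code, entry in registry.entries.items():
        if merge.canonical(code) == code:
            kept[code] = entry
    return BodyMapRegistry(kept, version=f"{registry.version}-merged-{len(kept)}")


def encode_location(code: int, registry: BodyMapRegistry) -> np.ndarray:
    """One-hot encode ``code``: registry rank for positives, last slot for -1."""
    vec = np.zeros(registry.encoding_length, dtype=np.float32)
    vec[registry.index_of(code)] = 1.0
    return vec


def encode_locations(codes, registry: BodyMapRegistry) -> np.ndarray:
    """Vectorized :func:`encode_location` over a sequence of codes."""
    idx = np.array([registry.index_of(c) for c in codes])
    out = np.zeros((len(idx), registry.encoding_length), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def decode_location(encoding: np.ndarray, registry: BodyMapRegistry) -> int:
    """Inverse of :func:`encode_location`; rejects zero or multi-hot vectors."""
    vec = np.asarray(encoding)
    if vec.shape != (registry.encoding_length,):
        raise BodyMapError(
            f"encoding length {vec.shape} does not match registry "
            f"(expected {registry.encoding_length})"
        )
    hot = np.flatnonzero(vec == 1)
    if hot.size != 1 or not np.all((vec == 0) | (vec == 1)):
        raise BodyMapError("malformed one-hot encoding (need exactly one 1)")
    idx = int(hot[0])
    if idx == len(registry):
        return BACKGROUND_CODE
    return registry.codes[idx]


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = [
            f"[{'PASS' if c.passed else 'FAIL'}] {c.name}: {c.detail}" for c in self.checks
        ]
        return "\n".join(lines)


def validate_registry(
    registry: BodyMapRegistry,
    merge: MergeMap,
    expected_original: int | None = None,
    expected_simplified: int | None = None,
) -> ValidationReport:
    """Check registry/merge structural invariants; failures are reported, not raised."""
    checks: list[ValidationCheck] = []

    def add(name: str, passed: bool, detail: str) -> None:
        checks.append(ValidationCheck(name, bool(passed), detail))

    add(
        "codes-positive-unique",
        all(c > 0 for c in registry.codes),
        f"{len(registry)} codes",
    )
    keys_ok = all(c in registry for c in merge.mapping)
    targets_ok = all(t in registry for t in merge.mapping.values())
    add("merge-keys-in-registry", keys_ok, "every merged code is a registry member")
    add("merge-canonicals-in-registry", targets_ok, "every canonical is a registry member")
    self_mapped = all(
        merge.mapping.get(t, t) == t for t in merge.mapping.values()
    )
    add("canonicals-self-mapped", self_mapped, "canonical codes map to themselves")
    idempotent = all(
        merge.canonical(merge.canonical(c)) == merge.canonical(c) for c in registry.codes
    )
    add("translation-idempotent", idempotent, "translate is a projection")
    try:
        simplified = apply_merge(registry, merge)
        n_simpl = len(simplified)
    except BodyMapError as exc:
        simplified = None
        n_simpl = -1
        add("merge-applies", False, str(exc))
    removed = merge.n_removed
    if simplified is not None:
        add(
            "removed-count-consistent",
            len(registry) - n_simpl == removed,
            f"{len(registry)} - {n_simpl} == {removed} removed codes",
        )
    if expected_original is not None:
        add(
            "original-count",
            len(registry) == expected_original,
            f"expected {expected_original}, found {len(registry)}",
        )
    if expected_simplified is not None:
        add(
            "simplified-count",
            n_simpl == expected_simplified,
            f"expected {expected_simplified}, found {n_simpl}",
        )
    return ValidationReport(checks)


def packaged_registry_path() -> Path:
    """Path of the packaged 484-location original registry."""
    return Path(resources.files("woundmm") / "data" / "bodymap.csv")


def packaged_merge_path() -> Path:
    """Path of the packaged merge map (484 -> 323 locations)."""
    return Path(resources.files("woundmm") / "data" / "bodymap_merge.csv")


def load_packaged_registry() -> BodyMapRegistry:
    reg = load_registry(packaged_registry_path(), version="original-484")
    return reg


def load_packaged_merge() -> MergeMap:
    return load_merge_map(packaged_merge_path())


def load_packaged_simplified() -> BodyMapRegistry:
    reg = apply_merge(load_packaged_registry(), load_packaged_merge())
    return BodyMapRegistry(reg.entries, version="simplified-323")
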
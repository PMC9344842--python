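"""Deterministic use-case corpus: fiber manufacture/measurement records.

Emulates the two-phase engineered-living-materials workflow the
platform was designed around: Phase 1 manufactures core-shell hydrogel
fibers (HEK293 cells in bovine collagen, sheathed in alginate
crosslinked with CaCl₂), Phase 2 characterizes them by inner/outer
diameter at three points from optical-microscope images.  Records use
the packaged manufacture/measurement templates (Dublin Core plus the
wet-lab fields); payloads are seeded pseudo-random bytes standing in
for instrument output.

Corruption modes plant exactly one known violation per corrupted
record, so validator tests can assert the precise violation kind.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import ConfigError
from .schema import MetadataRecord, MetadataTemplate, builtin_registry

CORRUPTION_MODES = (
    "drop-required",
    "bad-language",
    "off-vocabulary",
    "bad-date",
    "bad-number",
)

#: corruption mode -> the violation kind it must trigger
MODE_VIOLATION = {
    "drop-required": "missing-required",
    "bad-language": "bad-language-code",
    "off-vocabulary": "not-in-vocabulary",
    "bad-date": "bad-date",
    "bad-number": "bad-number",
}


def manufacture_template() -> MetadataTemplate:
    """Dublin Core plus the six fabrication parameters (21 fields)."""
    return builtin_registry().get("fiber-manufacture")


def measurement_template() -> MetadataTemplate:
    """Dublin Core plus the eight characterization fields (23 fields)."""
    return builtin_registry().get("fiber-measurement")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic corpus."""

    seed: int = 42
    n_records: int = 10
    corruption_modes: tuple[str, ...] = ()
    payload_size: int = 1024

    def __post_init__(self) -> None:
        unknown = set(self.corruption_modes) - set(CORRUPTION_MODES)
        if unknown:
            raise ConfigError(f"unknown corruption modes: {sorted(unknown)}")
        object.__setattr__(self, "corruption_modes", tuple(self.corruption_modes))


@dataclass(frozen=True)
class FixtureItem:
    record: MetadataRecord
    payload: bytes
    expected_valid: bool
    planted_violation: str | None = None  # violation kind, when corrupted


_CREATORS = ("tissue engineering group", "sensors group")
_CONTRIBUTORS = ("k. hirayama", "s. novik", "p. vazquez")
_LANGUAGES = ("en", "no", "de")


def _dublin_values(rng: random.Random, i: int, phase: str) -> dict[str, str]:
    day = rng.randrange(1, 29)
    month = rng.randrange(1, 13)
    return {
        "Creator": _CREATORS[0] if phase == "manufacture" else _CREATORS[1],
        "Contributor": rng.choice(_CONTRIBUTORS),
        "Publisher": "university of oslo",
        "Title": f"fiber {phase} batch {i:03d}",
        "Date": f"2021-{month:02d}-{day:02d}",
        "Language": rng.choice(_LANGUAGES),
        "Format": "text/csv" if phase == "manufacture" else "image/tiff",
        "Subject": "engineered living materials; tissue fibers",
        "Description": f"{phase} run {i:03d} of core-shell hydrogel fibers",
        "Identifier": f"hub:fiber:{phase}:{i:04d}",
        "Relation": "hub:project:fiber-pilot",
        "Source": "hybrid technology hub",
        "Type": "dataset",
        "Coverage": "Oslo, Norway",
        "Rights": "CC-BY-4.0",
    }


def _manufacture_values(rng: random.Random, i: int) -> dict[str, str]:
    values = _dublin_values(rng, i, "manufacture")
    values.update(
        {
            "cell_type": "HEK293",
            "collagen_concentration_mg_per_ml": "4",
            "cell_density_cells_per_ml": "1e8",
            "alginate_flow_ul_per_min": str(rng.choice((180, 200, 220))),
            "cacl2_concentration_mM": "100",
            "incubation_temp_C": "37",
        }
    )
    return values


def _measurement_values(rng: random.Random, i: int) -> dict[str, str]:
    values = _dublin_values(rng, i, "measurement")
    for which, lo, hi in (("inner", 90.0, 130.0), ("outer", 180.0, 260.0)):
        for p in (1, 2, 3):
            values[f"{which}_diameter_um_point{p}"] = f"{rng.uniform(lo, hi):.1f}"
    values["n_images"] = str(rng.randrange(5, 10))
    values["microscope_id"] = "uio-phys-om1"
    return values


def _corrupt(values: dict[str, str], mode: str, rng: random.Random, phase: str) -> None:
    if mode == "drop-required":
        values.pop(rng.choice(("Title", "Creator", "Rights")))
    elif mode == "bad-language":
        values["Language"] = rng.choice(("eng", "nor", "e", "engl", "en-GB"))
    elif mode == "off-vocabulary":
        values["cell_type"] = "yeast"
    elif mode == "bad-date":
        values["Date"] = rng.choice(("03/12/2021", "2021-13-40", "yesterday"))
    elif mode == "bad-number":
        key = "collagen_concentration_mg_per_ml" if phase == "manufacture" else "n_images"
        values[key] = "four"


def generate_corpus(spec: FixtureSpec) -> list[FixtureItem]:
    """Build a deterministic corpus of (record, payload, expected flag).

    Records alternate between the manufacture and measurement phases.
    When corruption modes are given, every odd-indexed item is
    corrupted, cycling through the modes; the planted violation kind is
    attached so tests can assert it exactly.  The same spec always
    yields a byte-identical corpus.
    """
    rng = random.Random(spec.seed)
    items: list[FixtureItem] = []
    n_corrupted = 0
    for i in range(spec.n_records):
        phase = "manufacture" if i % 2 == 0 else "measurement"
        # off-vocabulary only exists on the manufacture template
        if spec.corruption_modes and i % 2 == 1:
            mode = spec.corruption_modes[n_corrupted % len(spec.corruption_modes)]
            if mode == "off-vocabulary":
                phase = "manufacture"
        if phase == "manufacture":
            values = _manufacture_values(rng, i)
            template_id = "fiber-manufacture"
        else:
            values = _measurement_values(rng, i)
            template_id = "fiber-measurement"
        planted = None
        if spec.corruption_modes and i % 2 == 1:
            mode = spec.corruption_modes[n_corrupted % len(spec.corruption_modes)]
            _corrupt(values, mode, rng, phase)
            planted = MODE_VIOLATION[mode]
            n_corrupted += 1
        payload = rng.randbytes(spec.payload_size)
        items.append(
            FixtureItem(
                record=MetadataRecord(template_id=template_id, values=values),
                payload=payload,
                expected_valid=planted is None,
                planted_violation=planted,
            )
        )
    return items


def write_corpus(items: list[FixtureItem], out_dir) -> None:
    """Emit record JSON files and payload files for CLI/demo use."""
    import json
    from pathlib import Path

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    for i, item in enumerate(items):
        (root / f"record_{i:03d}.json").write_text(
            json.dumps(item.record.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
        )
        (root / f"payload_{i:03d}.bin").write_bytes(item.payload)
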
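"""Experiment design: which samples exist, how they were crosslinked and paired.

A ChIRP pulldown experiment runs three crosslinking arms (native / UV /
formaldehyde).  Each pulldown sample is captured with a probe combination
(one of several single antisense probes, or all probes pooled) and is paired
with a control sample: beads with no probe, scrambled probes, or a probe
with no homology to the target RNA (the non-homologous control used for the
native arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DesignError, FormatError

CROSSLINK_MODES = ("native", "uv", "formaldehyde")
ROLES = ("pulldown", "control")
CONTROL_TYPES = ("no_probe", "scrambled", "nonhomologous_probe", "not_applicable")

DESIGN_COLUMNS = [
    "sample_id",
    "crosslink_mode",
    "probe_combo",
    "role",
    "control_type",
    "paired_control_id",
]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    crosslink_mode: str
    probe_combo: str  # probe id, "pooled", or "" for none
    role: str
    control_type: str
    paired_control_id: str  # "" for controls


@dataclass
class ExperimentDesign:
    """An ordered collection of :class:`Sample` rows with pairing validation."""

    samples: list[Sample]
    probe_panel: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise DesignError("duplicate sample ids in design")
        by_id = {s.sample_id: s for s in self.samples}
        for s in self.samples:
            if s.crosslink_mode not in CROSSLINK_MODES:
                raise DesignError(f"unknown crosslink mode {s.crosslink_mode!r}")
            if s.role not in ROLES:
                raise DesignError(f"unknown role {s.role!r}")
            if s.control_type not in CONTROL_TYPES:
                raise DesignError(f"unknown control type {s.control_type!r}")
            if s.role == "pulldown":
                if not s.paired_control_id:
                    raise DesignError(f"pulldown {s.sample_id} names no control")
                ctrl = by_id.get(s.paired_control_id)
                if ctrl is None or ctrl.role != "control":
                    raise DesignError(
                        f"pulldown {s.sample_id} pairs to missing control "
                        f"{s.paired_control_id!r}"
                    )
                if ctrl.crosslink_mode != s.crosslink_mode:
                    raise DesignError(
                        f"pulldown {s.sample_id} pairs across crosslink modes"
                    )
            if self.probe_panel and s.probe_combo not in ("", "pooled"):
                if s.probe_combo not in self.probe_panel:
                    raise DesignError(
                        f"probe {s.probe_combo!r} not in declared panel"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def pulldowns(self, mode: str | None = None) -> list[Sample]:
        out = [s for s in self.samples if s.role == "pulldown"]
        if mode is not None:
            out = [s for s in out if s.crosslink_mode == mode]
        return out

    def controls(self, mode: str | None = None) -> list[Sample]:
        out = [s for s in self.samples if s.role == "control"]
        if mode is not None:
            out = [s for s in out if s.crosslink_mode == mode]
        return out

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise DesignError(f"no sample {sample_id!r} in design")

    def probe_combos(self, mode: str = "native") -> list[str]:
        seen: list[str] = []
        for s in self.pulldowns(mode):
            if s.probe_combo and s.probe_combo not in seen:
                seen.append(s.probe_combo)
        return seen

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [s.sample_id, s.crosslink_mode, s.probe_combo, s.role,
                 s.control_type, s.paired_control_id]
                for s in self.samples
            ],
            columns=DESIGN_COLUMNS,
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_probe_panel(n_probes: int = 5) -> tuple[str, ...]:
    return tuple(f"P{i}" for i in range(1, n_probes + 1))


def default_design(
    n_native_replicates: int = 4,
    n_uv_replicates: int = 1,
    n_formaldehyde_replicates: int = 1,
    n_probes: int = 5,
) -> ExperimentDesign:
    """The canonical pulldown design used throughout the package.

    Native arm: each of the single probes is run once against its own
    non-homologous-probe control (these drive the probe-combination vote);
    the pooled-probe capture is run in ``n_native_replicates`` replicates,
    each with a paired control, and supplies the replicated contrast for the
    native t-test.  UV and formaldehyde arms each run replicated
    pooled-probe pulldowns against no-probe / scrambled controls.
    """
    panel = default_probe_panel(n_probes)
    samples: list[Sample] = []
    for probe in panel:
        cid = f"native_{probe}_ctrl"
        samples.append(Sample(cid, "native", probe, "control",
                              "nonhomologous_probe", ""))
        samples.append(Sample(f"native_{probe}", "native", probe, "pulldown",
                              "not_applicable", cid))
    for r in range(1, n_native_replicates + 1):
        cid = f"native_pooled_r{r}_ctrl"
        samples.append(Sample(cid, "native", "pooled", "control",
                              "nonhomologous_probe", ""))
        samples.append(Sample(f"native_pooled_r{r}", "native", "pooled",
                              "pulldown", "not_applicable", cid))
    for r in range(1, n_uv_replicates + 1):
        cid = f"uv_r{r}_ctrl"
        samples.append(Sample(cid, "uv", "", "control", "no_probe", ""))
        samples.append(Sample(f"uv_r{r}", "uv", "pooled", "pulldown",
                              "not_applicable", cid))
    for r in range(1, n_formaldehyde_replicates + 1):
        cid = f"fa_r{r}_ctrl"
        samples.append(Sample(cid, "formaldehyde", "", "control",
                              "scrambled", ""))
        samples.append(Sample(f"fa_r{r}", "formaldehyde", "pooled", "pulldown",
                              "not_applicable", cid))
    return ExperimentDesign(samples, probe_panel=panel)


def parse_design(path: str | Path) -> ExperimentDesign:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design table missing column(s): {', '.join(missing)}")
    samples = [
        Sample(
            r.sample_id.strip(), r.crosslink_mode.strip(), r.probe_combo.strip(),
            r.role.strip(), r.control_type.strip(), r.paired_control_id.strip(),
        )
        for r in df.itertuples()
    ]
    panel = tuple(
        sorted({s.probe_combo for s in samples
                if s.probe_combo not in ("", "pooled")})
    )
    return ExperimentDesign(samples, probe_panel=panel)
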
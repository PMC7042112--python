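"""Named condition presets for the synthetic generator.

Each preset encodes, as generator ground truth, the published summary values
for one pharmacological comparison in rat artery endothelium: paired control
and drug-incubated arms of IP3-uncaging or acetylcholine (ACh) stimulation,
the ryanodine/caffeine panel, and the isolated endothelial-patch protocol.
"±" values in those summaries are standard errors of the mean over n animals,
so the between-animal SD encoded here is SEM * sqrt(n).

Every numeric field carries a provenance note (``ArmSpec.provenance``) saying
which printed summary it encodes, in plain words.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ArmSpec",
    "PhaseSpec",
    "ConditionPreset",
    "preset",
    "available_presets",
]

#: Default number of repeat recordings per animal and condition
#: (uncaging and ACh records were acquired in triplicate).
DEFAULT_TECH_REPS = 3

#: Cell-level amplitude SD as a fraction of the animal mean. The published
#: per-cell scatter plots show wide cell-to-cell spread; a 30% coefficient of
#: variation is a realistic single choice applied to every arm.
CELL_CV = 0.30


@dataclass(frozen=True)
class ArmSpec:
    """One arm (condition state) of a paired comparison."""

    name: str
    mean_peak_amp: float      # true mean peak dF/F0 across animals
    between_animal_sd: float  # SD of per-animal mean peak dF/F0
    between_cell_sd: float    # SD of per-cell amplitude about the animal mean
    responder_fraction: float = 1.0
    spontaneous_fraction: float = 0.05
    oscillation_rate_hz: float = 0.1   # Poisson rate after the first transient
    rise_tau_s: float = 0.3
    decay_tau_s: float = 3.0
    stimulus: str = "uncaging"         # uncaging | agonist_flow | none
    stim_frame: int = 150
    n_animals: int = 5
    n_tech_reps: int = DEFAULT_TECH_REPS
    n_cells: int = 30
    n_frames: int = 1000
    frame_rate_hz: float = 10.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.between_animal_sd < 0 or self.between_cell_sd < 0:
            raise ValueError("SDs must be >= 0")
        for f in (self.responder_fraction, self.spontaneous_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.stimulus not in ("uncaging", "agonist_flow", "none"):
            raise ValueError(f"unknown stimulus kind {self.stimulus!r}")
        if self.stimulus != "none" and self.mean_peak_amp <= 0:
            raise ValueError("stimulated arms need mean_peak_amp > 0")
        if self.stim_frame >= self.n_frames:
            raise ValueError("stim_frame must precede the end of the record")
        if not (0 < self.rise_tau_s < self.decay_tau_s):
            raise ValueError("need decay_tau_s > rise_tau_s > 0")
        if min(self.n_animals, self.n_tech_reps, self.n_cells) < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class PhaseSpec:
    """A window of the sequential patch-perfusion protocol."""

    name: str
    n_frames: int
    # fraction of cells carrying >= 1 event in this window
    active_fraction: float
    # mean event amplitude (dF/F0) for active cells in this window
    mean_amp: float
    stimulated: bool = False  # stimulus-locked transient at window start


@dataclass(frozen=True)
class ConditionPreset:
    name: str
    arms: tuple[ArmSpec, ...] = ()
    phases: tuple[PhaseSpec, ...] = ()  # only the patch protocol uses phases
    n_animals: int = 5
    n_cells: int = 100
    frame_rate_hz: float = 10.0
    notes: str = ""

    def arm(self, name: str) -> ArmSpec:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"preset {self.name!r} has no arm {name!r}; "
                       f"arms: {[a.name for a in self.arms]}")


def _sd(sem: float, n: int) -> float:
    return sem * math.sqrt(n)


def _arm(name, mean, sem, n, *, stimulus, stim_frame, n_cells, n_frames,
         osc=0.1, responder=1.0, spont=0.05, reps=DEFAULT_TECH_REPS,
         note="") -> ArmSpec:
    return ArmSpec(
        name=name,
        mean_peak_amp=mean,
        between_animal_sd=_sd(sem, n),
        between_cell_sd=CELL_CV * mean,
        responder_fraction=responder,
        spontaneous_fraction=spont,
        oscillation_rate_hz=osc,
        stimulus=stimulus,
        stim_frame=stim_frame,
        n_animals=n,
        n_tech_reps=reps,
        n_cells=n_cells,
        n_frames=n_frames,
        provenance={
            "mean_peak_amp": f"printed summary {mean} ± {sem} (SEM), n = {n}: {note}",
            "between_animal_sd": f"SEM {sem} at n = {n} converted to SD = SEM*sqrt(n)",
        },
    )


def _ip3(name, mean, sem, n, note, **kw) -> ArmSpec:
    """Localized IP3-uncaging arm: 1,000 frames at 10 fps, flash at 15 s,
    ~30 cells inside the ~70 um photolysis disc."""
    return _arm(name, mean, sem, n, stimulus="uncaging", stim_frame=150,
                n_cells=30, n_frames=1000, osc=0.1, note=note, **kw)


def _ach(name, mean, sem, n, note, **kw) -> ArmSpec:
    """ACh-perfusion arm: 2,000 frames at 10 fps, ~100 cells; agonist
    arrival set to frame 200 (perfusion onset is not instantaneous and the
    published protocol does not pin it to a frame)."""
    return _arm(name, mean, sem, n, stimulus="agonist_flow", stim_frame=200,
                n_cells=100, n_frames=2000, osc=0.2, note=note, **kw)


def _ryr(name, mean, sem, n, note) -> ArmSpec:
    """Ryanodine/caffeine panel arm: 1,000 frames, stimulus at 30 s."""
    return _arm(name, mean, sem, n, stimulus="agonist_flow", stim_frame=300,
                n_cells=100, n_frames=1000, osc=0.1, note=note)


def _build_registry() -> dict[str, ConditionPreset]:
    reg: dict[str, ConditionPreset] = {}

    reg["ip3_fk506"] = ConditionPreset(
        name="ip3_fk506",
        arms=(
            _ip3("control", 1.41, 0.10, 5,
                 "IP3-uncaging peak dF/F0 before FK506"),
            _ip3("fk506", 1.81, 0.20, 5,
                 "IP3-uncaging peak dF/F0 after 10 uM FK506 (30 min)"),
        ),
        n_animals=5, n_cells=30,
        notes="FK506 potentiates IP3-evoked release (paired, n = 5).",
    )

    reg["ach_fk506"] = ConditionPreset(
        name="ach_fk506",
        arms=(
            _ach("control", 0.78, 0.10, 6,
                 "ACh-evoked peak dF/F0 before FK506"),
            _ach("fk506", 0.85, 0.10, 6,
                 "ACh-evoked peak dF/F0 after 10 uM FK506 (30 min)"),
        ),
        n_animals=6, n_cells=100,
        notes="FK506 potentiates ACh-evoked release (paired, n = 6).",
    )

    reg["ip3_cypermethrin"] = ConditionPreset(
        name="ip3_cypermethrin",
        arms=(
            _ip3("control", 1.45, 0.14, 7,
                 "IP3-uncaging peak dF/F0 before cypermethrin"),
            _ip3("cypermethrin", 1.73, 0.14, 7,
                 "IP3-uncaging peak dF/F0 after 10 uM cypermethrin"),
            _ip3("cypermethrin_fk506", 1.90, 0.19, 7,
                 "IP3-uncaging peak dF/F0 after cypermethrin + FK506"),
        ),
        n_animals=7, n_cells=30,
        notes=("Body text reports n = 7 for the IP3 comparison while the "
               "figure legend says n = 5; the body text is followed here."),
    )

    reg["ach_cypermethrin"] = ConditionPreset(
        name="ach_cypermethrin",
        arms=(
            _ach("control", 0.88, 0.11, 5,
                 "ACh-evoked peak dF/F0 before cypermethrin"),
            _ach("cypermethrin", 1.05, 0.12, 5,
                 "ACh-evoked peak dF/F0 after 10 uM cypermethrin"),
            _ach("cypermethrin_fk506", 0.75, 0.16, 5,
                 "ACh-evoked peak dF/F0 after cypermethrin + FK506"),
        ),
        n_animals=5, n_cells=100,
        notes=("Body text reports n = 5 for the ACh comparison while the "
               "figure legend says n = 7; the body text is followed here."),
    )

    reg["ip3_okadaic"] = ConditionPreset(
        name="ip3_okadaic",
        arms=(
            _ip3("control", 1.30, 0.12, 6,
                 "IP3-uncaging peak dF/F0 before okadaic acid"),
            _ip3("okadaic", 1.52, 0.17, 6,
                 "IP3-uncaging peak dF/F0 after 5 uM okadaic acid"),
        ),
        n_animals=6, n_cells=30,
        notes="Okadaic acid potentiates IP3-evoked release (paired, n = 6).",
    )

    reg["ip3_okadaic_fk506"] = ConditionPreset(
        name="ip3_okadaic_fk506",
        arms=(
            _ip3("okadaic", 1.52, 0.17, 6,
                 "IP3-uncaging peak dF/F0 under okadaic acid alone"),
            _ip3("okadaic_fk506", 1.33, 0.19, 6,
                 "IP3-uncaging peak dF/F0 after FK506 added on top of "
                 "okadaic acid (FK506 now reduces release)"),
        ),
        n_animals=6, n_cells=30,
        notes="With calcineurin already inhibited, FK506 reduces release.",
    )

    reg["ip3_rapamycin"] = ConditionPreset(
        name="ip3_rapamycin",
        arms=(
            _ip3("control", 1.45, 0.25, 5,
                 "IP3-uncaging peak dF/F0 before rapamycin"),
            _ip3("rapamycin", 1.48, 0.23, 5,
                 "IP3-uncaging peak dF/F0 after 10 uM rapamycin "
                 "(no significant change: the null comparison)"),
        ),
        n_animals=5, n_cells=30,
        notes="Rapamycin does not alter IP3-evoked release (paired, n = 5).",
    )

    reg["ryanodine_panel"] = ConditionPreset(
        name="ryanodine_panel",
        arms=(
            _ryr("ach_baseline", 0.30, 0.06, 5,
                 "baseline ACh response of the ryanodine/caffeine panel "
                 "(arbitrary fluorescence units read as dF/F0)"),
            _ryr("ryanodine", 0.05, 0.02, 5,
                 "response to 30 uM ryanodine alone"),
            _ryr("ryanodine_caffeine", 0.006, 0.003, 5,
                 "ryanodine added during 10 mM caffeine"),
            _ryr("ryanodine_incub_caffeine", 0.001, 0.001, 5,
                 "caffeine after 15 min ryanodine incubation"),
            _ryr("ach_ryanodine", 0.54, 0.08, 5,
                 "ACh applied in the continued presence of ryanodine"),
        ),
        n_animals=5, n_cells=100,
        notes=("Ryanodine-receptor agonism evokes essentially no endothelial "
               "Ca2+ release; ACh responses persist. Values below the "
               "detection floor (0.05 dF/F0) are expected to read out as 0."),
    )

    # Isolated aortic endothelial patches: sequential baseline -> ACh ->
    # caffeine perfusion on the same cells. The published windows are 8 min
    # each; the preset uses 60-s windows, which carry the same per-cell
    # activity fractions at desk scale.
    reg["patch_ach_caffeine"] = ConditionPreset(
        name="patch_ach_caffeine",
        phases=(
            PhaseSpec("baseline", 600, 0.48, 0.35),
            PhaseSpec("ach", 600, 0.96, 0.80, stimulated=True),
            PhaseSpec("caffeine", 600, 0.16, 0.35),
        ),
        n_animals=5, n_cells=100,
        notes=("Patch protocol: 96% of cells respond to ACh, 16% are active "
               "under caffeine, 48% show baseline spontaneous activity "
               "(paired, n = 5 patches)."),
    )

    return reg


_REGISTRY = _build_registry()


def available_presets() -> list[str]:
    return sorted(_REGISTRY)


def preset(name: str) -> ConditionPreset:
    """Look up a named condition preset.

    Raises
    ------
    KeyError
        If the name is unknown; the message lists the available presets.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
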
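"""Declarative demographic-scenario configuration.

A :class:`ScenarioConfig` fully specifies one simulation experiment: the
genome (length, mutation and recombination rates, number of replicate
chromosomes), the deme structure and migration regime, scheduled demographic
events (population splits, admixture, size changes, introduction of a
chromosomal inversion), and the sampling scheme applied at the final
generation.

Time convention: all event times are expressed in *generations before
present*; generation 0 is the generation that is sampled.  The simulator
converts these to forward generation indices internally.

The module also provides the expected-``NeVk`` reference trajectories that
estimates are compared against (for a panmictic Wright-Fisher population the
variance-of-progeny effective size ``NeVk`` equals the diploid census size
``N``; for several contemporaneous demes the total reference is the sum of
the deme sizes), plus utilities to rescale a full-size design down to a
desk-size one while preserving the compound parameters ``N*mu``, ``N*c`` and
``N*m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

EVENT_KINDS = ("split", "admix", "resize", "introduce_inversion")
FAMILIES = ("panmictic", "synthetic", "reciprocal_migration", "source_sink", "inversion")
SAMPLE_SCHEMES = ("single_deme", "pooled_equal")
INVERSION_MODES = ("balanced", "recent_low")


class ValidationError(ValueError):
    """Raised when a scenario document violates the schema.

    ``field`` names the offending key.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    """Genome model: a uniformly recombining sequence replicated as chromosomes.

    ``map_rate`` is Morgans per bp (1 cM/Mb = 1e-8 M/bp).  ``n_chromosomes``
    independent replicates of the sequence are simulated and pooled at the
    estimation stage, mimicking a multi-chromosome genome.
    """

    sequence_length_bp: int = 250_000_000
    mutation_rate: float = 2e-9
    map_rate: float = 1e-8
    n_chromosomes: int = 20

    def __post_init__(self):
        if self.sequence_length_bp <= 0:
            raise ValidationError("sequence_length_bp", "must be > 0")
        if not (0 < self.mutation_rate < 1):
            raise ValidationError("mutation_rate", "must be in (0, 1)")
        if self.map_rate <= 0:
            raise ValidationError("map_rate", "must be > 0")
        if self.n_chromosomes < 1:
            raise ValidationError("n_chromosomes", "must be >= 1")

    @property
    def map_length_morgans(self) -> float:
        return self.sequence_length_bp * self.map_rate


@dataclass(frozen=True)
class DemographyEvent:
    """One scheduled demographic event.

    ``time`` is in generations before present; the event takes effect when
    the generation at ``time - 1`` before present is produced (i.e. the new
    configuration has existed for ``time`` reproduction steps at sampling).

    kinds and params:
      * ``split``: ``daughter_sizes`` — the single ancestral deme is replaced
        by len(daughter_sizes) demes, each founded by sampling parents from
        the ancestral deme.
      * ``admix``: ``size`` — all current demes merge into one deme of
        ``size`` diploids whose parents are drawn uniformly across sources.
      * ``resize``: ``deme``, ``size`` — deme changes to ``size`` offspring.
      * ``introduce_inversion``: ``deme``, ``copies`` — flag ``copies``
        haplotypes (uniformly chosen) as carrying the inversion.
    """

    time: int
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError("events.time", "must be >= 0")
        if self.kind not in EVENT_KINDS:
            raise ValidationError("events.kind", f"unknown kind {self.kind!r}")


@dataclass(frozen=True)
class InversionConfig:
    """A chromosomal inversion segregating under frequency-dependent selection.

    Recombination is suppressed inside ``[start_bp, end_bp)`` in inversion
    heterozygotes.  Carrier fitness is ``1 - (q - 0.5) * selection_coefficient``
    with ``q`` the current inversion frequency, which balances ``q`` near 0.5.
    ``balanced`` mode introduces a single inversion-bearing haplotype at the
    start of the run and lets selection drive it to intermediate frequency
    (replicates that lose it are retried); ``recent_low`` introduces
    ``initial_copies`` haplotypes ``introduce_time`` generations before
    present, so the inversion is still at low frequency when sampled.
    """

    start_bp: int = 100_000_000
    end_bp: int = 150_000_000
    selection_coefficient: float = 0.2
    target_mode: str = "balanced"
    introduce_time: int = 50
    initial_copies: int = 1

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValidationError("inversion", "end_bp must exceed start_bp")
        if self.target_mode not in INVERSION_MODES:
            raise ValidationError("inversion.target_mode", f"unknown mode {self.target_mode!r}")
        if not (0 < self.selection_coefficient < 2):
            raise ValidationError("inversion.selection_coefficient", "must be in (0, 2)")


@dataclass(frozen=True)
class SampleSpec:
    """How the genotyped cohort is drawn at generation 0.

    ``single_deme`` samples ``total_sample`` individuals from ``focal_deme``;
    ``pooled_equal`` samples ``total_sample / n_demes`` from every deme.
    """

    total_sample: int = 100
    scheme: str = "single_deme"
    focal_deme: int = 0

    def __post_init__(self):
        if self.total_sample < 2:
            raise ValidationError("sample.total_sample", "must be >= 2")
        if self.scheme not in SAMPLE_SCHEMES:
            raise ValidationError("sample.scheme", f"unknown scheme {self.scheme!r}")
        if self.focal_deme < 0:
            raise ValidationError("sample.focal_deme", "must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterization of one demographic scenario."""

    name: str = "scenario"
    family: str = "panmictic"
    deme_sizes: tuple = (1000,)
    migration_rate: float = 0.0
    migration_period: int = 1
    total_generations: int = 10_000
    events: tuple = ()
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    inversion: InversionConfig | None = None
    sample: SampleSpec = field(default_factory=SampleSpec)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError("family", f"unknown family {self.family!r}")
        if not self.deme_sizes:
            raise ValidationError("deme_sizes", "at least one deme required")
        if any(n < 2 for n in self.deme_sizes):
            raise ValidationError("deme_sizes", "every deme size must be >= 2")
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ValidationError("migration_rate", "must be in [0, 1]")
        if self.migration_period < 1:
            raise ValidationError("migration_period", "must be >= 1")
        if self.total_generations < 1:
            raise ValidationError("total_generations", "must be >= 1")
        if self.family == "source_sink" and len(self.deme_sizes) != 2:
            raise ValidationError("deme_sizes", "source_sink requires exactly 2 demes (source, sink)")
        split_times = [e.time for e in self.events if e.kind == "split"]
        admix_times = [e.time for e in self.events if e.kind == "admix"]
        for t_admix in admix_times:
            for t_split in split_times:
                if t_admix >= t_split:
                    raise ValidationError(
                        "events",
                        f"admix at {t_admix} must postdate (be more recent than) split at {t_split}",
                    )
        for e in self.events:
            if e.time > self.total_generations:
                raise ValidationError("events.time", "event predates the start of the simulation")
        if self.inversion is not None:
            if not (0 <= self.inversion.start_bp < self.genome.sequence_length_bp):
                raise ValidationError("inversion.start_bp", "outside the sequence")
            if self.inversion.end_bp > self.genome.sequence_length_bp:
                raise ValidationError("inversion.end_bp", "outside the sequence")

    @property
    def n_demes_initial(self) -> int:
        return len(self.deme_sizes)

    def deme_sizes_at(self, generations_before_present: int) -> tuple:
        """Diploid deme sizes at a given generation before present.

        An event scheduled at time ``t`` affects generations more recent than
        ``t`` (i.e. ``g <= t - 1``).
        """
        g = generations_before_present
        sizes = list(self.deme_sizes)
        for e in sorted(self.events, key=lambda e: -e.time):
            if e.time <= g:
                continue
            if e.kind == "split":
                sizes = list(e.params["daughter_sizes"])
            elif e.kind == "admix":
                sizes = [e.params["size"]]
            elif e.kind == "resize":
                sizes[e.params["deme"]] = e.params["size"]
        return tuple(sizes)


@dataclass(frozen=True)
class NeVkReference:
    """Piecewise-constant expected-NeVk trajectory.

    ``breakpoints`` are event times (generations before present, descending
    implicitly by segment); segment ``i`` covers ``[breakpoints[i+1],
    breakpoints[i])`` with the convention that the first segment extends back
    to the start of the simulation.  ``all_demes`` is the sum over
    contemporaneous demes (the upper reference line); ``focal_deme`` is the
    size of the sampled deme (the lower line).
    """

    breakpoints: tuple  # descending generation-before-present segment starts
    all_demes: tuple
    focal_deme: tuple

    def value_at(self, generations_before_present: float, line: str = "all") -> float:
        values = self.all_demes if line == "all" else self.focal_deme
        g = generations_before_present
        # ascending scan: the governing segment is the one with the smallest
        # breakpoint strictly greater than g
        for start, v in sorted(zip(self.breakpoints, values)):
            if g < start:
                return float(v)
        return float(values[0])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def expected_nevk(scenario: ScenarioConfig) -> NeVkReference:
    """Expected NeVk reference lines for a scenario.

    For a panmictic Wright-Fisher deme NeVk equals the diploid census size;
    with several contemporaneous demes the total reference is the sum of all
    deme sizes, and the focal (lower) line is the sampled deme's own size.
    """
    times = sorted({scenario.total_generations}
                   | {e.time for e in scenario.events if e.kind in ("split", "admix", "resize")},
                   reverse=True)
    breakpoints, all_vals, focal_vals = [], [], []
    focal = scenario.sample.focal_deme
    for t in times:
        sizes = scenario.deme_sizes_at(t - 1)  # sizes in force just after the event
        breakpoints.append(t)
        all_vals.append(int(sum(sizes)))
        focal_vals.append(int(sizes[min(focal, len(sizes) - 1)]))
    return NeVkReference(tuple(breakpoints), tuple(all_vals), tuple(focal_vals))


def rescale_scenario(scenario: ScenarioConfig, factor: float) -> ScenarioConfig:
    """Rescale a design to desk size, preserving diffusion-compound parameters.

    Deme sizes are divided by ``factor``; mutation, map and effective
    per-generation migration rates are multiplied by it; event times and the
    total run length are divided by it.  This keeps ``N*mu``, ``N*c``,
    ``N*m`` and times measured in units of ``N`` generations unchanged, so
    the rescaled run explores the same diffusion.  For pulsed migration the
    *effective* rate ``m / period`` is what scales: the period is divided by
    ``factor`` (floored at 1) and the per-pulse rate adjusted accordingly.
    The inversion selection coefficient is likewise multiplied by ``factor``
    (capped below 2 to keep fitness positive), preserving ``N*s``.
    """
    if factor < 1:
        raise ValidationError("factor", "must be >= 1")
    if factor == 1:
        return scenario

    def scale_size(n):
        m = round(n / factor)
        if m < 2:
            raise ValidationError("factor", f"deme size {n} / {factor} falls below 2")
        return m

    def scale_time(t):
        return max(1, round(t / factor)) if t > 0 else 0

    new_period = max(1, round(scenario.migration_period / factor))
    new_m = scenario.migration_rate * factor * new_period / scenario.migration_period
    if new_m > 1.0:
        raise ValidationError("migration_rate", "rescaled migration rate exceeds 1")

    new_events = []
    for e in scenario.events:
        params = dict(e.params)
        if e.kind == "split":
            params["daughter_sizes"] = [scale_size(n) for n in params["daughter_sizes"]]
        elif e.kind in ("admix", "resize"):
            params["size"] = scale_size(params["size"])
        new_events.append(DemographyEvent(scale_time(e.time), e.kind, params))

    new_inversion = scenario.inversion
    if new_inversion is not None:
        new_inversion = replace(
            new_inversion,
            selection_coefficient=min(new_inversion.selection_coefficient * factor, 1.9),
            introduce_time=scale_time(new_inversion.introduce_time),
        )

    return replace(
        scenario,
        deme_sizes=tuple(scale_size(n) for n in scenario.deme_sizes),
        migration_rate=new_m,
        migration_period=new_period,
        total_generations=max(1, round(scenario.total_generations / factor)),
        events=tuple(new_events),
        genome=replace(
            scenario.genome,
            mutation_rate=scenario.genome.mutation_rate * factor,
            map_rate=scenario.genome.map_rate * factor,
        ),
        inversion=new_inversion,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: ScenarioConfig) -> dict:
    d = {
        "name": scenario.name,
        "family": scenario.family,
        "deme_sizes": list(scenario.deme_sizes),
        "migration_rate": scenario.migration_rate,
        "migration_period": scenario.migration_period,
        "total_generations": scenario.total_generations,
        "seed": scenario.seed,
        "genome": {
            "sequence_length_bp": scenario.genome.sequence_length_bp,
            "mutation_rate": scenario.genome.mutation_rate,
            "map_rate": scenario.genome.map_rate,
            "n_chromosomes": scenario.genome.n_chromosomes,
        },
        "sample": {
            "total_sample": scenario.sample.total_sample,
            "scheme": scenario.sample.scheme,
            "focal_deme": scenario.sample.focal_deme,
        },
        "events": [
            {"time": e.time, "kind": e.kind, **e.params} for e in scenario.events
        ],
    }
    if scenario.inversion is not None:
        inv = scenario.inversion
        d["inversion"] = {
            "start_bp": inv.start_bp,
            "end_bp": inv.end_bp,
            "selection_coefficient": inv.selection_coefficient,
            "target_mode": inv.target_mode,
            "introduce_time": inv.introduce_time,
            "initial_copies": inv.initial_copies,
        }
    return d


def serialize_scenario(scenario: ScenarioConfig) -> str:
    """YAML document for a scenario; ``parse_scenario`` inverts it exactly."""
    return yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True)


_GENOME_KEYS = {"sequence_length_bp", "mutation_rate", "map_rate", "n_chromosomes"}
_SAMPLE_KEYS = {"total_sample", "scheme", "focal_deme"}
_INV_KEYS = {"start_bp", "end_bp", "selection_coefficient", "target_mode",
             "introduce_time", "initial_copies"}
_TOP_KEYS = {"name", "family", "deme_sizes", "migration_rate", "migration_period",
             "total_generations", "seed", "genome", "sample", "events", "inversion"}


def scenario_from_dict(d: dict) -> ScenarioConfig:
    if not isinstance(d, dict):
        raise ValidationError("document", "top level must be a mapping")
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ValidationError(sorted(unknown)[0], "unknown key")
    for sub, allowed in (("genome", _GENOME_KEYS), ("sample", _SAMPLE_KEYS)):
        if sub in d and d[sub] is not None:
            bad = set(d[sub]) - allowed
            if bad:
                raise ValidationError(f"{sub}.{sorted(bad)[0]}", "unknown key")
    events = []
    for i, ev in enumerate(d.get("events", []) or []):
        ev = dict(ev)
        try:
            time = int(ev.pop("time"))
            kind = ev.pop("kind")
        except KeyError as exc:
            raise ValidationError(f"events[{i}]", f"missing {exc.args[0]!r}") from None
        events.append(DemographyEvent(time, kind, ev))
    inversion = None
    if d.get("inversion") is not None:
        bad = set(d["inversion"]) - _INV_KEYS
        if bad:
            raise ValidationError(f"inversion.{sorted(bad)[0]}", "unknown key")
        inversion = InversionConfig(**d["inversion"])
    return ScenarioConfig(
        name=d.get("name", "scenario"),
        family=d.get("family", "panmictic"),
        deme_sizes=tuple(int(n) for n in d.get("deme_sizes", (1000,))),
        migration_rate=float(d.get("migration_rate", 0.0)),
        migration_period=int(d.get("migration_period", 1)),
        total_generations=int(d.get("total_generations", 10_000)),
        events=tuple(events),
        genome=GenomeConfig(**(d.get("genome") or {})),
        inversion=inversion,
        sample=SampleSpec(**(d.get("sample") or {})),
        seed=int(d.get("seed", 0)),
    )


def parse_scenario(config_text: str) -> ScenarioConfig:
    """Parse and validate a YAML scenario document."""
    try:
        d = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ValidationError("document", f"not valid YAML: {exc}") from exc
    return scenario_from_dict(d)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def builtin_presets() -> dict:
    """Full-scale scenario presets for every study condition, plus desk-scale
    variants (suffix ``-desk``) rescaled by a factor of 10 (5 for the
    panmictic design) with a 10 Mb x 4-chromosome genome."""
    presets: dict[str, ScenarioConfig] = {}
    genome_full = GenomeConfig(250_000_000, 2e-9, 1e-8, 20)

    presets["panmictic"] = ScenarioConfig(
        name="panmictic", family="panmictic", deme_sizes=(1000,),
        total_generations=10_000, genome=genome_full,
        sample=SampleSpec(100, "single_deme", 0))

    # synthetic (admixed) populations: k ancestral demes of 1000 diverged
    # T = 1000 generations ago, mixed t generations ago into one deme.
    for k, tag in ((5, "5pop"), (2, "2pop")):
        for n_mix in (100, 1000):
            for t in (5, 10, 20, 50):
                name = f"synthetic-{tag}-n{n_mix}-t{t}"
                presets[name] = ScenarioConfig(
                    name=name, family="synthetic", deme_sizes=(1000,),
                    total_generations=10_000, genome=genome_full,
                    events=(
                        DemographyEvent(1000, "split", {"daughter_sizes": [1000] * k}),
                        DemographyEvent(t, "admix", {"size": n_mix}),
                    ),
                    sample=SampleSpec(100, "single_deme", 0))

    # two demes of 1000 with continuous reciprocal migration
    for nm, m in ((1, 0.001), (2, 0.002), (5, 0.005), (10, 0.01), (20, 0.02)):
        name = f"two-deme-nm{nm}"
        presets[name] = ScenarioConfig(
            name=name, family="reciprocal_migration", deme_sizes=(1000, 1000),
            migration_rate=m, total_generations=10_000, genome=genome_full,
            sample=SampleSpec(100, "pooled_equal"))
    presets["two-deme-pulse-nm1"] = ScenarioConfig(
        name="two-deme-pulse-nm1", family="reciprocal_migration",
        deme_sizes=(1000, 1000), migration_rate=0.01, migration_period=10,
        total_generations=10_000, genome=genome_full,
        sample=SampleSpec(100, "pooled_equal"))

    # island model: ten demes of 500
    for nm, m in ((0.05, 0.0001), (0.2, 0.0004), (0.5, 0.001),
                  (1, 0.002), (2, 0.004), (20, 0.04)):
        name = f"island10-nm{nm}"
        presets[name] = ScenarioConfig(
            name=name, family="reciprocal_migration", deme_sizes=(500,) * 10,
            migration_rate=m, total_generations=10_000, genome=genome_full,
            sample=SampleSpec(100, "pooled_equal"))

    # source-sink: deme 0 is the large source (never receives migrants),
    # deme 1 the focal sink.  Default Nm = 10 into the sink.
    ss_events = {
        "constant": (),
        "decline": (DemographyEvent(10, "resize", {"deme": 1, "size": 100}),),
        "bottleneck": (DemographyEvent(30, "resize", {"deme": 1, "size": 100}),
                       DemographyEvent(10, "resize", {"deme": 1, "size": 1000})),
        "expansion": (DemographyEvent(10, "resize", {"deme": 1, "size": 10_000}),),
    }
    for tag, events in ss_events.items():
        name = f"source-sink-{tag}"
        presets[name] = ScenarioConfig(
            name=name, family="source_sink", deme_sizes=(10_000, 1000),
            migration_rate=0.01, total_generations=10_000, genome=genome_full,
            events=events, sample=SampleSpec(100, "single_deme", 1))

    # closed population with a 50 Mb inversion in the middle of the sequence
    inv_events = {
        "constant": (),
        "drop": (DemographyEvent(10, "resize", {"deme": 0, "size": 100}),),
        "bottleneck": (DemographyEvent(30, "resize", {"deme": 0, "size": 100}),
                       DemographyEvent(10, "resize", {"deme": 0, "size": 1000})),
    }
    for tag, events in inv_events.items():
        name = f"inversion-{tag}"
        presets[name] = ScenarioConfig(
            name=name, family="inversion", deme_sizes=(1000,),
            total_generations=10_000, genome=genome_full, events=events,
            inversion=InversionConfig(100_000_000, 150_000_000, 0.2, "balanced"),
            sample=SampleSpec(100, "single_deme", 0))
    presets["inversion-low-freq"] = ScenarioConfig(
        name="inversion-low-freq", family="inversion", deme_sizes=(1000,),
        total_generations=10_000, genome=genome_full,
        inversion=InversionConfig(100_000_000, 150_000_000, 0.2, "recent_low",
                                  introduce_time=50, initial_copies=100),
        sample=SampleSpec(100, "single_deme", 0))

    # desk-scale variants: rescaled dynamics on a smaller pooled genome
    desk_genome_overrides = dict(sequence_length_bp=10_000_000, n_chromosomes=4)
    for name in list(presets):
        sc = presets[name]
        factor = 5 if name == "panmictic" else 10
        desk = rescale_scenario(sc, factor)
        changes = dict(name=f"{name}-desk",
                       genome=replace(desk.genome, **desk_genome_overrides))
        if desk.inversion is not None:
            # keep the inverted fraction of the genome at 20%, mid-sequence
            changes["inversion"] = replace(desk.inversion,
                                           start_bp=4_000_000, end_bp=6_000_000)
        desk = replace(desk, **changes)
        presets[f"{name}-desk"] = desk
    return presets


def list_presets() -> list:
    """Names of the packaged scenario presets."""
    root = resources.files("structne").joinpath("presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ScenarioConfig:
    """Load a packaged preset by name."""
    root = resources.files("structne").joinpath("presets")
    path = root.joinpath(f"{name}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no preset named {name!r}; see list_presets()") from None
    return parse_scenario(text)
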
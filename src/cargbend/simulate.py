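"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be simulated here: circular
permutation mobility series, phasing series, saturation binding curves,
circularization time courses and promoter sequences with planted CArG
motifs. Each generator is a deterministic function of a
:class:`SimulationConfig` and its arguments; with ``noise == 0`` the outputs
lie exactly on the corresponding model curves.

Default truth parameters reflect the measured system: an N10-class bend of
93 degrees, in-phase spacing 55 bp at a 10.5 bp/turn helical repeat, KD of
4.515 (probe-amount units), and circularization rates ordered in-phase >
out-of-phase with both probes ligating more slowly than free DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bending import PermutationLane, PermutationSeries
from .binding import BindingSeries, CircularizationSeries
from .exceptions import CargBendError
from .io import SequenceRecord
from .motifs import MotifHit, builtin_patterns, get_pattern, scan_sequence
from .phasing import PhasingLane, PhasingSeries, spacing_from_linker

#: enzyme labels used for simulated permutation lanes, mirroring a typical
#: restriction panel
_ENZYME_PANEL = ("MluI", "BglII", "XhoI", "EcoRV", "SmaI", "StuI", "RsaI", "BamHI")

#: free-probe migration, arbitrary gel units, held constant across lanes
FREE_MIGRATION = 10.0


def default_truth() -> dict:
    return {
        "bend_angle_deg": 93.0,  # N10-class bend
        "mu_E": 0.8,             # fastest-complex relative mobility
        "bend_center": None,     # None -> mid-probe
        "baseline": 0.6,         # phasing sinusoid midline
        "amplitude": 0.1,
        "s0": 55.0,              # in-phase spacing, bp
        "repeat": 10.5,          # helical repeat, bp/turn
        "bmax": 1.0,
        "kd": 4.515,             # N10-class dissociation constant
        "k_in": 0.12,            # per-minute circularization rates
        "k_out": 0.05,
        "plateau_in": 75.0,      # percent of the no-protein control
        "plateau_out": 55.0,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Seed, per-assay noise levels and true parameter values.

    Noise units: ``mobility_sigma`` in relative-mobility units,
    ``binding_sigma`` as a fraction of bmax, ``circ_sigma`` in percent
    minicircle.
    """

    seed: int = 0
    mobility_sigma: float = 0.005
    binding_sigma: float = 0.02
    circ_sigma: float = 2.0
    truth: dict = field(default_factory=default_truth)

    def __post_init__(self) -> None:
        for name in ("mobility_sigma", "binding_sigma", "circ_sigma"):
            if getattr(self, name) < 0:
                raise CargBendError(f"{name} must be >= 0")
        merged = default_truth()
        merged.update(self.truth)
        object.__setattr__(self, "truth", merged)

    def with_truth(self, **kwargs) -> "SimulationConfig":
        t = dict(self.truth)
        t.update(kwargs)
        return replace(self, truth=t)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per (seed, assay-stream) pair."""
        return np.random.default_rng([self.seed, stream])


def gen_permutation_series(
    cfg: SimulationConfig, n_lanes: int = 8, probe_length: float = 230.0
) -> tuple[PermutationSeries, dict]:
    """Simulate a circular-permutation mobility series from the cosine model."""
    if n_lanes < 4:
        raise CargBendError("need at least 4 lanes")
    t = cfg.truth
    center = t["bend_center"] if t["bend_center"] is not None else probe_length / 2
    mu_E = t["mu_E"]
    mu_M = mu_E * math.cos(math.radians(t["bend_angle_deg"]) / 2)
    a, b = (mu_M + mu_E) / 2, (mu_M - mu_E) / 2
    positions = np.linspace(0.1 * probe_length, 0.9 * probe_length, n_lanes)
    rng = cfg.rng(1)
    rel = a + b * np.cos(np.pi * (positions - center) / probe_length)
    rel = rel + rng.normal(0.0, cfg.mobility_sigma, size=n_lanes)
    rel = np.clip(rel, 1e-6, 1.0)
    lanes = [
        PermutationLane(
            enzyme=_ENZYME_PANEL[i % len(_ENZYME_PANEL)],
            site_center=float(p),
            free_migration=FREE_MIGRATION,
            complex_migration=float(r * FREE_MIGRATION),
        )
        for i, (p, r) in enumerate(zip(positions, rel))
    ]
    truth = {
        "bend_angle_deg": t["bend_angle_deg"],
        "bend_center": center,
        "mu_M": mu_M,
        "mu_E": mu_E,
    }
    return PermutationSeries(probe_length=probe_length, lanes=lanes), truth


def gen_phasing_series(
    cfg: SimulationConfig, linkers=(12, 14, 16, 18, 20)
) -> tuple[PhasingSeries, dict]:
    """Simulate a phasing series from the sinusoidal mobility model."""
    t = cfg.truth
    spacings = np.array([spacing_from_linker(l) for l in linkers], dtype=float)
    rng = cfg.rng(2)
    rel = t["baseline"] - t["amplitude"] * np.cos(
        2 * np.pi * (spacings - t["s0"]) / t["repeat"]
    )
    rel = rel + rng.normal(0.0, cfg.mobility_sigma, size=len(spacings))
    rel = np.clip(rel, 1e-6, 1.0)
    lanes = [
        PhasingLane(
            linker=float(l),
            spacing=float(s),
            free_migration=FREE_MIGRATION,
            complex_migration=float(r * FREE_MIGRATION),
        )
        for l, s, r in zip(linkers, spacings, rel)
    ]
    truth = {
        "s0": t["s0"],
        "repeat": t["repeat"],
        "baseline": t["baseline"],
        "amplitude": t["amplitude"],
    }
    return PhasingSeries(lanes=lanes), truth


def gen_binding_series(
    cfg: SimulationConfig, x_grid=None, label: str = "N10"
) -> tuple[BindingSeries, dict]:
    """Simulate a one-site saturation binding curve."""
    t = cfg.truth
    if x_grid is None:
        x_grid = np.geomspace(0.5, 32.0, 8)
    x = np.asarray(x_grid, dtype=float)
    rng = cfg.rng(3)
    y = t["bmax"] * x / (t["kd"] + x)
    y = y + rng.normal(0.0, cfg.binding_sigma * t["bmax"], size=len(x))
    series = BindingSeries(points=list(zip(x, y)), label=label)
    return series, {"bmax": t["bmax"], "kd": t["kd"]}


def gen_circularization(
    cfg: SimulationConfig, times=tuple(range(0, 61, 10))
) -> tuple[CircularizationSeries, CircularizationSeries, dict]:
    """Simulate paired in-phase / out-of-phase minicircle time courses."""
    t = cfg.truth
    times = np.asarray(times, dtype=float)
    rng = cfg.rng(4)
    out = []
    for k, plateau, label in (
        (t["k_in"], t["plateau_in"], "in_phase"),
        (t["k_out"], t["plateau_out"], "out_of_phase"),
    ):
        pct = plateau * (1 - np.exp(-k * times))
        pct = pct + rng.normal(0.0, cfg.circ_sigma, size=len(times))
        pct = np.clip(pct, 0.0, None)
        if times[0] == 0:
            pct[0] = 0.0  # ligation has not started
        out.append(
            CircularizationSeries(
                points=list(zip(times, pct)), phase_label=label, protein_present=True
            )
        )
    truth = {k: t[k] for k in ("k_in", "k_out", "plateau_in", "plateau_out")}
    return out[0], out[1], truth


def _sample_motif(rng: np.random.Generator, pattern, n_atypical: int) -> str:
    """Draw a motif instance with exactly ``n_atypical`` deviating positions."""
    bases = [
        sorted(allowed)[rng.integers(len(allowed))] for allowed in pattern.positions
    ]
    if n_atypical:
        idx = rng.choice(len(pattern), size=n_atypical, replace=False)
        for i in sorted(int(j) for j in idx):
            outside = sorted(set("ACGT") - set(pattern.positions[i]))
            if not outside:
                raise CargBendError(
                    f"pattern {pattern.name} position {i} admits every base; "
                    "cannot plant a deviation there"
                )
            bases[i] = outside[rng.integers(len(outside))]
    return "".join(bases)


def gen_promoters(
    cfg: SimulationConfig,
    n_seqs: int = 5,
    length: int = 500,
    plant_spec=(("canonical", 0), ("n10_like", 0)),
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Random promoter sequences with planted CArG motifs plus a truth table.

    ``plant_spec`` lists (pattern_name, n_atypical) pairs; each is planted
    once per sequence at a random non-overlapping position. The truth table
    records the planted hits and, additionally, every window that matches
    any builtin pattern at mismatch budget 0 (accidental background matches
    included), found by scanning the emitted sequences.
    """
    rng = cfg.rng(5)
    records: list[SequenceRecord] = []
    planted_rows = []
    for si in range(n_seqs):
        seq = list(rng.choice(list("ACGT"), size=length))
        seq_id = f"promoter_{si + 1}"
        occupied: list[tuple[int, int]] = []
        for pattern_name, n_atyp in plant_spec:
            pattern = get_pattern(pattern_name)
            k = len(pattern)
            motif = _sample_motif(rng, pattern, n_atyp)
            placed = False
            for _ in range(200):
                start = int(rng.integers(0, length - k + 1))
                if all(start + k <= s or start >= e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise CargBendError(
                    f"could not place {pattern_name} without overlap in "
                    f"{length} bp ({len(plant_spec)} plants requested)"
                )
            seq[start : start + k] = list(motif)
            occupied.append((start, start + k))
            planted_rows.append(
                {
                    "seq_id": seq_id,
                    "start": start,
                    "end": start + k,
                    "strand": "+",
                    "pattern_name": pattern_name,
                    "n_atypical": n_atyp,
                    "matched_seq": motif,
                    "planted": True,
                }
            )
        records.append(SequenceRecord(id=seq_id, seq="".join(seq)))
    # brute-force census of exact (budget 0) matches in the emitted sequences
    truth_rows = list(planted_rows)
    planted_keys = {
        (r["seq_id"], r["start"], r["strand"], r["pattern_name"]) for r in planted_rows
    }
    for rec in records:
        for hit in scan_sequence(rec.id, rec.seq, builtin_patterns(), 0, True):
            if (hit.seq_id, hit.start, hit.strand, hit.pattern_name) in planted_keys:
                continue
            truth_rows.append(
                {
                    "seq_id": hit.seq_id,
                    "start": hit.start,
                    "end": hit.end,
                    "strand": hit.strand,
                    "pattern_name": hit.pattern_name,
                    "n_atypical": hit.n_atypical,
                    "matched_seq": hit.matched_seq,
                    "planted": False,
                }
            )
    columns = [
        "seq_id", "start", "end", "strand", "pattern_name",
        "n_atypical", "matched_seq", "planted",
    ]
    truth = pd.DataFrame(truth_rows, columns=columns)
    truth = truth.sort_values(["seq_id", "start", "strand"]).reset_index(drop=True)
    return records, truth
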
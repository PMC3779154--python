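"""Synthetic qHTS screen generator with known ground-truth pharmacology.

Emulates a primary-cell cytotoxicity screen: a compound library with planted
pharmacological archetypes is "screened" against CLL-like and normal-like
samples, producing raw 1536-well luminescence plate stacks in inter-plate
titration layout with control columns, bracketing DMSO-only plates,
multiplicative spatial artifacts and log-normal well noise.

Archetypes
----------
* ``inactive`` — flat response (|yinf - y0| < 5 points),
* ``pan_cytotoxic`` — full-efficacy kill at similar potency in every sample,
* ``partial`` — kill plateauing below the 60% efficacy gate,
* ``top_only`` — steep response only at the top tested concentration,
* ``selective`` — potent full kill in CLL samples, strongly right-shifted
  and low-efficacy in normal samples.

The signal model is ``raw = baseline * (1/sb + (1 - 1/sb) * s) * spatial *
noise`` where ``s = max(1 + y/100, 0)`` is the surviving-cell fraction and
``sb`` the DMSO/full-kill signal ratio: full kill leaves the background
luminescence floor ``baseline/sb``, and control-anchored normalization
exactly inverts the mapping.

Per-sample potencies are drawn log-normally around a compound-level center
(default spread 0.3 log10 units) to emulate inter-patient variation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import plates
from .doseresponse import four_param_logistic
from .errors import InvalidArgumentError, LookupFailure
from .io import RawPlateStack, STACK_COLUMNS
from .plates import ConcentrationSeries, make_series

ARCHETYPES = ("inactive", "pan_cytotoxic", "partial", "top_only", "selective")

#: default archetype mix of the synthetic library
DEFAULT_FRACTIONS = {
    "inactive": 0.70,
    "pan_cytotoxic": 0.12,
    "partial": 0.08,
    "top_only": 0.05,
    "selective": 0.05,
}

DEFAULT_CLL_SAMPLES = tuple(f"CLL-{i}" for i in range(1, 7))
DEFAULT_NORMAL_SAMPLES = tuple(f"N-{i}" for i in range(1, 6))

#: doxorubicin positive-control truth used for the column-2 titration
DOX_TRUTH = {"y0": 0.0, "yinf": -100.0, "ac50": 4.5, "hill": 1.5}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model of the simulated plate reader.

    ``sb_ratio`` is the DMSO-to-full-kill signal ratio; ``well_cv`` the
    fractional CV of multiplicative log-normal well noise;
    ``spatial_amplitude`` the strength of the corner-gradient-plus-edge
    artifact field (mean 1 over the plate).  ``spatial_ramp`` optionally
    ramps the amplitude linearly from the first to the last plate.
    """

    plate_baseline: float = 10000.0
    sb_ratio: float = 11.2
    well_cv: float = 0.05
    spatial_amplitude: float = 0.10
    spatial_ramp: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sb_ratio <= 1:
            raise InvalidArgumentError("sb_ratio must be > 1")
        if self.well_cv < 0:
            raise InvalidArgumentError("well_cv must be >= 0")


@dataclass
class TruthTable:
    """Planted per-compound x sample pharmacology plus the generation recipe."""

    table: pd.DataFrame = field(repr=False)
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def compound_ids(self) -> list[str]:
        return self.table["compound_id"].drop_duplicates().tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].drop_duplicates().tolist()

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        sub = self.table[self.table["sample_id"] == sample_id]
        if sub.empty:
            raise LookupFailure(f"sample {sample_id!r} not in truth table")
        return sub


def _archetype_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Exact largest-remainder apportionment of archetype counts."""
    if set(fractions) - set(ARCHETYPES):
        raise InvalidArgumentError(f"unknown archetypes: {set(fractions) - set(ARCHETYPES)}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9 or any(f < 0 for f in fractions.values()):
        raise InvalidArgumentError("archetype fractions must be >= 0 and sum to 1")
    quotas = {a: n * fractions.get(a, 0.0) for a in ARCHETYPES}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    for a in sorted(ARCHETYPES, key=lambda a: quotas[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    return counts


def generate_library(
    n_compounds: int,
    fractions: dict[str, float] | None = None,
    cll_samples: tuple[str, ...] = DEFAULT_CLL_SAMPLES,
    normal_samples: tuple[str, ...] = DEFAULT_NORMAL_SAMPLES,
    seed: int = 0,
    sigma_log10: float = 0.3,
) -> TruthTable:
    """Draw a truth table: one 4PL parameter set per compound x sample.

    Deterministic for a fixed seed.  ``sigma_log10`` is the log10 spread of
    per-sample potency around each compound's center.
    """
    if n_compounds < 1:
        raise InvalidArgumentError("n_compounds must be >= 1")
    fractions = dict(DEFAULT_FRACTIONS if fractions is None else fractions)
    counts = _archetype_counts(n_compounds, fractions)
    rng = np.random.default_rng([int(seed), 0xA5])

    archetypes = np.repeat(
        [a for a in ARCHETYPES for _ in range(counts[a])], 1
    )
    archetypes = archetypes[rng.permutation(n_compounds)]
    width = max(4, len(str(n_compounds)))
    compound_ids = [f"C{i+1:0{width}d}" for i in range(n_compounds)]
    samples = [(s, "cll") for s in cll_samples] + [(s, "normal") for s in normal_samples]

    rows = []
    for cid, arch in zip(compound_ids, archetypes):
        hill = float(rng.uniform(1.5, 3.0))
        if arch == "inactive":
            center, yinf_c = 10.0 ** rng.uniform(-1, 1), float(rng.uniform(-4.0, 0.0))
        elif arch == "pan_cytotoxic":
            center, yinf_c = 10.0 ** rng.uniform(-1.0, 0.3), float(rng.uniform(-100.0, -90.0))
        elif arch == "partial":
            center, yinf_c = 10.0 ** rng.uniform(-1.0, 0.3), float(rng.uniform(-55.0, -40.0))
        elif arch == "top_only":
            center = 10.0 ** rng.uniform(np.log10(35.0), np.log10(60.0))
            yinf_c = float(rng.uniform(-100.0, -80.0))
            hill = float(rng.uniform(3.0, 6.0))
        else:  # selective
            center, yinf_c = 10.0 ** rng.uniform(-1.0, 0.3), float(rng.uniform(-100.0, -90.0))
        fold = 10.0 ** rng.uniform(1.0, 1.7)  # selective CLL->normal potency shift
        yinf_normal_sel = float(rng.uniform(-45.0, -25.0))

        for sid, group in samples:
            ac50 = center * 10.0 ** rng.normal(0.0, sigma_log10)
            yinf = yinf_c
            if arch == "selective" and group == "normal":
                ac50 = center * fold * 10.0 ** rng.normal(0.0, sigma_log10)
                yinf = yinf_normal_sel
            rows.append((cid, sid, group, arch, 0.0, yinf, float(ac50), hill))

    table = pd.DataFrame(
        rows,
        columns=["compound_id", "sample_id", "group", "archetype", "y0", "yinf", "ac50_uM", "hill"],
    )
    config = {
        "n_compounds": int(n_compounds),
        "fractions": fractions,
        "cll_samples": list(cll_samples),
        "normal_samples": list(normal_samples),
        "sigma_log10": float(sigma_log10),
    }
    return TruthTable(table=table, seed=int(seed), config=config)


def spatial_field(amplitude: float) -> np.ndarray:
    """Corner-to-corner gradient plus edge depression, normalized to mean 1."""
    rr = np.linspace(0.0, 1.0, plates.N_ROWS)[:, None]
    cc = np.linspace(0.0, 1.0, plates.N_COLS)[None, :]
    grad = (rr + cc) / 2.0 - 0.5
    edge = np.zeros((plates.N_ROWS, plates.N_COLS))
    edge[0, :] = edge[-1, :] = 1.0
    edge[:, 0] = edge[:, -1] = 1.0
    fld = 1.0 + amplitude * grad - 0.5 * amplitude * edge
    return fld / fld.mean()


def _viability(y: np.ndarray, sb_ratio: float) -> np.ndarray:
    surviving = np.maximum(1.0 + y / 100.0, 0.0)
    return 1.0 / sb_ratio + (1.0 - 1.0 / sb_ratio) * surviving


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(sample_id.encode())])


def generate_sample_screen(
    truth: TruthTable,
    sample_id: str,
    noise: NoiseModel | None = None,
    series: ConcentrationSeries | None = None,
    seed: int | None = None,
) -> RawPlateStack:
    """Simulate one sample's raw plate stack.

    The stack holds, in order: one DMSO-only plate, the inter-plate
    titration (for each plate position, one plate per concentration,
    descending), and a trailing DMSO-only plate.
    """
    noise = noise or NoiseModel()
    series = series or make_series(57.0, 5.0, 8)
    seed = truth.seed if seed is None else seed
    rng = _sample_rng(seed, sample_id)

    sub = truth.for_sample(sample_id).set_index("compound_id")
    compound_ids = truth.compound_ids
    layout = plates.assign_compound_wells(len(compound_ids))
    n_positions = max(p for p, _ in layout) + 1

    spec = plates.PlateSpec()
    role_grid = spec.role_grid()
    dox_conc = np.array([plates.titration_concentration(r) for r in range(1, plates.N_ROWS + 1)])
    y_dox = four_param_logistic(dox_conc, **DOX_TRUTH)

    # per-position scatter indices and truth parameter arrays
    pos_wells: dict[int, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    pos_params: dict[int, dict[str, np.ndarray]] = {}
    for p in range(n_positions):
        idx = [i for i, (pp, _) in enumerate(layout) if pp == p]
        r = np.array([layout[i][1].row - 1 for i in idx])
        c = np.array([layout[i][1].col - 1 for i in idx])
        cids = [compound_ids[i] for i in idx]
        pos_wells[p] = (r, c, cids)
        tp = sub.loc[cids]
        pos_params[p] = {k: tp[k].to_numpy(dtype=float) for k in ("y0", "yinf", "ac50_uM", "hill")}

    n_plates = 2 + n_positions * series.n_points
    plate_defs: list[tuple[str, str, int | None, float]] = [(f"{sample_id}-DMSO-A", "dmso", None, 0.0)]
    for p in range(n_positions):
        for k, conc in enumerate(series.values):
            plate_defs.append((f"{sample_id}-P{p+1:02d}-C{k+1}", "compound", p, float(conc)))
    plate_defs.append((f"{sample_id}-DMSO-B", "dmso", None, 0.0))

    ramp = noise.spatial_ramp
    frames = []
    for stack_index, (plate_id, kind, p, conc) in enumerate(plate_defs):
        if ramp is not None:
            t = stack_index / (n_plates - 1) if n_plates > 1 else 0.0
            amp = ramp[0] + (ramp[1] - ramp[0]) * t
        else:
            amp = noise.spatial_amplitude
        fld = spatial_field(amp)

        y = np.zeros((plates.N_ROWS, plates.N_COLS))
        conc_grid = np.zeros_like(y)
        cid_grid = np.full(y.shape, "", dtype=object)
        if kind == "dmso":
            roles = np.full(y.shape, plates.ROLE_DMSO, dtype=object)
        else:
            roles = role_grid.copy()
            y[:, plates.POS_TITRATION_COL - 1] = y_dox
            conc_grid[:, plates.POS_TITRATION_COL - 1] = dox_conc
            y[:, plates.POS_TOP_COL - 1] = -100.0
            conc_grid[:, plates.POS_TOP_COL - 1] = plates.POS_TOP_UM
            # unoccupied compound-area wells behave like solvent-only wells
            occupied = np.zeros(y.shape, dtype=bool)
            r, c, cids = pos_wells[p]
            occupied[r, c] = True
            roles[(roles == plates.ROLE_COMPOUND) & ~occupied] = plates.ROLE_EMPTY
            pars = pos_params[p]
            y[r, c] = four_param_logistic(
                conc, pars["y0"], pars["yinf"], pars["ac50_uM"], pars["hill"]
            )
            conc_grid[r, c] = conc
            cid_grid[r, c] = cids

        signal = noise.plate_baseline * _viability(y, noise.sb_ratio) * fld
        if noise.well_cv > 0:
            s = np.sqrt(np.log1p(noise.well_cv**2))
            signal = signal * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=signal.shape)

        rr, cc = np.meshgrid(
            np.arange(1, plates.N_ROWS + 1), np.arange(1, plates.N_COLS + 1), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "stack_index": stack_index,
                    "row": rr.ravel(),
                    "col": cc.ravel(),
                    "role": roles.ravel(),
                    "compound_id": cid_grid.ravel(),
                    "conc_uM": conc_grid.ravel(),
                    "value": signal.ravel(),
                }
            )
        )
    wells = pd.concat(frames, ignore_index=True)[STACK_COLUMNS]
    return RawPlateStack(sample_id=sample_id, wells=wells)


def generate_screen(
    truth: TruthTable,
    noise: NoiseModel | None = None,
    series: ConcentrationSeries | None = None,
    seed: int | None = None,
) -> dict[str, RawPlateStack]:
    """Simulate the whole screen: one raw stack per sample in the truth table."""
    return {
        sid: generate_sample_screen(truth, sid, noise=noise, series=series, seed=seed)
        for sid in truth.sample_ids
    }


def noise_config_dict(noise: NoiseModel) -> dict:
    d = asdict(noise)
    if d["spatial_ramp"] is not None:
        d["spatial_ramp"] = list(d["spatial_ramp"])
    return d
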
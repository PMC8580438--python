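"""Synthetic occurrence worlds with planted biogeographic provinces.

The generator emulates the kind of input the pipeline consumes in earnest: a
one-dimensional "coastline" of 0.5-degree cells, K provinces with distinct
species pools and gradational transition zones, environmental fields
correlated with the province structure, a latitudinal richness gradient,
log-scale variation in per-cell sampling effort, and record-level noise
(missing epithets, low-precision coordinates).  Because the true province of
every cell, the true species pools and the true diversity driver are known,
every pipeline stage can be tested as a parameter-recovery problem.

Within-cell assemblages are drawn with a Hoppe-urn (Ewens) process, whose
species-abundance distribution is exactly Fisher's log-series with parameter
alpha — so Fisher's alpha is not merely "meaningful" for these data, it is
the planted diversity of the cell, and its estimate is stable in sample
size.  Each cell's alpha is chosen so the expected species count at a
reference effort follows the configured richness trend.  Species identities
are assigned in pool-rank order (the urn's first-discovered species maps to
the pool's first rank), which makes communities within a province nested and
hence compositionally homogeneous.  Transition-zone cells split their
individuals between the two adjacent pools with linearly interpolated
weights.

Three named scenarios encode the competing hypotheses about what drives
richness:

* ``province_mediated`` — richness steps between provinces and is constant
  within them (biogeography is the proximate driver);
* ``direct_environment`` — a single species pool, richness a smooth function
  of temperature (the species-energy world);
* ``null_flat`` — constant richness, random species turnover (nothing to
  find).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .ingest import OccurrenceRecord, cell_key, ENV_VARIABLES

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthWorld",
    "generate_world",
    "generate_scenario",
    "SCENARIOS",
    "SynthError",
]

SCENARIOS = ("default", "province_mediated", "direct_environment", "null_flat")


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study conditions for one synthetic world.

    Defaults describe the reference world used throughout the test-suite:
    120 half-degree cells on a north-south coastline, five provinces with
    four-cell transition zones, 300-species pools sharing 10% with each
    neighbour, expected cell richness declining linearly from 80 (warm end)
    to 30 (cool end), and per-cell record counts log-uniform on
    [150, 5000].
    """

    n_cells: int = 120
    K: int = 5
    transition_width: int = 4
    pool_size: int = 300
    shared_fraction: float = 0.1
    richness_range: tuple[int, int] = (80, 30)
    effort_range: tuple[int, int] = (150, 5000)
    seed: int = 0

    # geometry: lower-corner latitude of the first (warmest) cell; cells run
    # southward; a "grid" topology wraps rows of grid_width cells for 2-D
    # spatial-weights tests
    lat_start: float = -5.0
    lon_start: float = 150.0
    topology: str = "line"
    grid_width: int = 10

    # environmental model: SST gradient endpoints (degC), per-province
    # offsets of scale env_province_offset added to province-tracking
    # variables, and observation noise
    sst_range: tuple[float, float] = (28.0, 10.0)
    env_province_offset: float = 1.0
    env_noise_sd: float = 0.3

    # reference effort at which the planted richness targets are expressed:
    # each cell's log-series alpha is chosen so that the expected species
    # count of a sample of this size equals the cell's target richness
    reference_effort: int = 1000

    # record-level noise: fractions of the *emitted* record stream that are
    # corrupted (extra records appended on top of the clean effort counts)
    frac_missing_epithet: float = 0.02
    frac_low_precision: float = 0.02

    def validate(self) -> None:
        if min(self.n_cells, self.K, self.pool_size, self.transition_width) < 0:
            raise SynthError("counts must be non-negative")
        if self.n_cells <= 0 or self.K <= 0 or self.pool_size <= 0:
            raise SynthError("n_cells, K and pool_size must be positive")
        if self.transition_width * (self.K - 1) >= self.n_cells:
            raise SynthError(
                "transition zones cover the whole coastline: need "
                "transition_width*(K-1) < n_cells"
            )
        if not 0 <= self.shared_fraction < 0.5:
            raise SynthError("shared_fraction must lie in [0, 0.5)")
        if self.effort_range[0] < 1 or self.effort_range[1] < self.effort_range[0]:
            raise SynthError("invalid effort range")
        if self.reference_effort <= max(self.richness_range):
            raise SynthError("reference_effort must exceed the richness targets")
        if max(self.richness_range) > self.pool_size:
            raise SynthError("richness target exceeds pool size")
        if not (0 <= self.frac_missing_epithet < 1
                and 0 <= self.frac_low_precision < 1
                and self.frac_missing_epithet + self.frac_low_precision < 1):
            raise SynthError("noise fractions must be proper fractions")
        if self.topology not in ("line", "grid"):
            raise SynthError("topology must be 'line' or 'grid'")


@dataclass
class SynthTruth:
    """Ground truth of a generated world."""

    labels: pd.Series                 # cell_key -> 'province<k>' or 'transition'
    pools: dict                       # 'province<k>' -> list of species names
    target_richness: pd.Series        # cell_key -> planted expected richness
    scenario: str
    n_clean_records: int
    n_noise_records: int
    mixture: pd.DataFrame             # cell_key x province weight matrix
    config: dict = field(default_factory=dict)


@dataclass
class SynthWorld:
    records: list
    env: pd.DataFrame                 # indexed by cell_key; lat/lon + 8 vars
    truth: SynthTruth

    def write(self, outdir) -> None:
        """Write occurrences.csv, env.csv and truth labels for inspection."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "scientificName": r.taxon_name,
                "decimalLatitude": r.lat_text,
                "decimalLongitude": r.lon_text,
                "id": r.source_id,
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(outdir / "occurrences.csv", index=False)
        self.env.to_csv(outdir / "env.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "scenario": self.truth.scenario,
                    "labels": self.truth.labels.to_dict(),
                    "target_richness": self.truth.target_richness.to_dict(),
                    "n_clean_records": self.truth.n_clean_records,
                    "n_noise_records": self.truth.n_noise_records,
                    "config": self.truth.config,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _species_name(i: int) -> str:
    """Unique, filter-passing binomial for global species index ``i``."""
    letters = []
    v = i
    for _ in range(4):
        letters.append(chr(ord("a") + v % 26))
        v //= 26
    return "Synthoconcha " + "".join(reversed(letters))


def _cell_positions(cfg: SynthConfig) -> list[tuple[float, float]]:
    """Lower corners of each cell, warm end first."""
    out = []
    for i in range(cfg.n_cells):
        if cfg.topology == "line":
            out.append((cfg.lat_start - 0.5 * i, cfg.lon_start))
        else:
            row, col = divmod(i, cfg.grid_width)
            out.append((cfg.lat_start - 0.5 * row, cfg.lon_start + 0.5 * col))
    return out


def _province_layout(cfg: SynthConfig) -> tuple[list[str], pd.DataFrame]:
    """Label each cell and assign pool-mixture weights.

    Core blocks of the K provinces are separated by ``transition_width``
    cells whose weights interpolate linearly between the flanking pools
    (endpoints excluded: the j-th of w transition cells carries weight
    ``j/(w+1)`` on the next province).
    """
    n, K, w = cfg.n_cells, cfg.K, cfg.transition_width
    core_total = n - w * (K - 1)
    base, extra = divmod(core_total, K)
    core_lengths = [base + (1 if k < extra else 0) for k in range(K)]
    labels: list[str] = []
    weights = np.zeros((n, K))
    i = 0
    for k in range(K):
        for _ in range(core_lengths[k]):
            labels.append(f"province{k + 1}")
            weights[i, k] = 1.0
            i += 1
        if k < K - 1:
            for j in range(1, w + 1):
                labels.append("transition")
                frac = j / (w + 1)
                weights[i, k] = 1.0 - frac
                weights[i, k + 1] = frac
                i += 1
    assert i == n
    wdf = pd.DataFrame(weights, columns=[f"province{k + 1}" for k in range(K)])
    return labels, wdf


def _build_pools(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Global species indices of each province pool, in commonness rank order.

    Adjacent pools share ``shared_fraction`` of their species; shared blocks
    get random ranks within each pool so overlap is spread across the
    abundance distribution.
    """
    K, P = cfg.K, cfg.pool_size
    n_shared = int(round(cfg.shared_fraction * P)) if K > 1 else 0
    pools: dict[str, np.ndarray] = {}
    next_id = 0
    shared_blocks = []
    for _ in range(K - 1):
        shared_blocks.append(np.arange(next_id, next_id + n_shared))
        next_id += n_shared
    for k in range(K):
        n_unique = P
        members = []
        if k > 0:
            members.append(shared_blocks[k - 1])
            n_unique -= n_shared
        if k < K - 1:
            members.append(shared_blocks[k])
            n_unique -= n_shared
        members.append(np.arange(next_id, next_id + n_unique))
        next_id += n_unique
        pool = np.concatenate(members)
        pools[f"province{k + 1}"] = rng.permutation(pool)
    return pools


def _decorrelating_permutation(K: int) -> np.ndarray:
    """Permutation of 0..K-1 minimizing |correlation| with position.

    Exhaustive for small K (deterministic tie-break by lexicographic order);
    a fixed pseudo-random shuffle otherwise.
    """
    if K == 1:
        return np.array([0])
    if K <= 7:
        import itertools

        pos = np.arange(K, dtype=float)
        best, best_r = None, np.inf
        for perm in itertools.permutations(range(K)):
            r = abs(np.corrcoef(pos, np.asarray(perm, dtype=float))[0, 1])
            if r < best_r - 1e-12:
                best, best_r = perm, r
        return np.array(best)
    return np.random.default_rng(12345).permutation(K)


def _alpha_for_target(target_S: float, reference_effort: int) -> float:
    """Log-series alpha whose expected richness at the reference effort is
    ``target_S`` (inverts ``S = alpha * ln(1 + n/alpha)``)."""
    from .diversity import fisher_alpha

    return fisher_alpha(int(round(target_S)), reference_effort)


def _hoppe_urn(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Species label (discovery rank, 0-based) of each of ``n`` individuals.

    Hoppe urn: the i-th individual founds a new species with probability
    ``alpha / (alpha + i)`` and otherwise copies a uniformly chosen earlier
    individual.  The resulting abundance distribution is Fisher's log-series
    with parameter ``alpha``.
    """
    labels = np.empty(n, dtype=np.int64)
    new_flags = rng.random(n) < alpha / (alpha + np.arange(n))
    copy_pick = rng.random(n)
    n_species = 0
    for i in range(n):
        if new_flags[i]:
            labels[i] = n_species
            n_species += 1
        else:
            labels[i] = labels[int(copy_pick[i] * i)]
    return labels


def _env_table(
    cfg: SynthConfig,
    positions: list[tuple[float, float]],
    weights: pd.DataFrame,
    rng: np.random.Generator,
    province_offsets: np.ndarray,
) -> pd.DataFrame:
    n = cfg.n_cells
    t = np.linspace(0.0, 1.0, n)           # 0 = warm end
    sst0, sst1 = cfg.sst_range
    off = weights.to_numpy() @ province_offsets
    noise = lambda s: rng.normal(0.0, s, n)  # noqa: E731
    sst = sst0 + (sst1 - sst0) * t + cfg.env_province_offset * off
    env = pd.DataFrame(
        {
            "lat": [p[0] for p in positions],
            "lon": [p[1] for p in positions],
            "sst_mean": sst + noise(cfg.env_noise_sd),
            "sst_sd": 0.8 + 1.5 * t + 0.2 * off + noise(0.1),
            "salinity_mean": 35.5 - 0.8 * t + 0.1 * off + noise(0.05),
            "salinity_sd": 0.25 + 0.3 * t + noise(0.03),
            "oxygen": 4.3 + 1.8 * t - 0.15 * off + noise(0.1),
            "nitrate": np.clip(0.5 + 5.0 * t + noise(0.2), 0.0, None),
            "silicate": np.clip(1.0 + 4.0 * t + 0.3 * off + noise(0.3), 0.0, None),
            "phosphate": np.clip(0.1 + 0.9 * t + noise(0.02), 0.0, None),
        }
    )
    keys = [
        cell_key((int(np.floor(2 * la)), int(np.floor(2 * lo))))
        for la, lo in positions
    ]
    env.index = pd.Index(keys, name="cell_id")
    return env


def _format_coord(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_world(
    config: Optional[SynthConfig] = None, scenario: str = "default"
) -> SynthWorld:
    """Generate one synthetic world: records, env table, ground truth.

    Fully deterministic given ``config.seed``.  ``scenario`` selects how the
    planted richness relates to provinces and temperature (see module
    docstring); ``"default"`` keeps the province structure with a linear
    latitudinal richness trend.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    if scenario not in SCENARIOS:
        raise SynthError(f"unknown scenario {scenario!r}; options: {SCENARIOS}")
    rng = np.random.default_rng(cfg.seed)

    positions = _cell_positions(cfg)
    labels, weights = _province_layout(cfg)
    province_offsets = rng.normal(0.0, 1.0, cfg.K)
    env = _env_table(cfg, positions, weights, rng, province_offsets)
    keys = list(env.index)

    # species pools ---------------------------------------------------------
    if scenario == "direct_environment":
        # one global pool, no compositional province structure
        global_pool = rng.permutation(np.arange(cfg.pool_size * cfg.K))
        pools = {"global": global_pool}
    elif scenario == "null_flat":
        pools = {"global": np.arange(cfg.pool_size * cfg.K)}
    else:
        pools = _build_pools(cfg, rng)

    # per-cell target richness ---------------------------------------------
    hi, lo = cfg.richness_range
    t = np.linspace(0.0, 1.0, cfg.n_cells)
    if scenario == "province_mediated":
        # stepped: one target per province, interpolated in transitions.
        # Targets are assigned to provinces in the order that minimizes their
        # correlation with coastline position, so the provincial signal is
        # identifiable against the smooth abiotic gradient (a monotone
        # assignment would be indistinguishable from a latitudinal trend).
        levels = np.linspace(hi, lo, cfg.K)
        prov_targets = np.round(levels[_decorrelating_permutation(cfg.K)])
        m = weights.to_numpy() @ prov_targets
    elif scenario == "direct_environment":
        # smooth in temperature (which is itself linear in position + noise)
        sst = env["sst_mean"].to_numpy()
        s0, s1 = cfg.sst_range
        m = lo + (hi - lo) * (sst - min(s0, s1)) / abs(s1 - s0)
        m = np.clip(m, min(hi, lo) * 0.5, cfg.pool_size * cfg.K)
    elif scenario == "null_flat":
        m = np.full(cfg.n_cells, (hi + lo) / 2.0)
    else:
        m = hi + (lo - hi) * t
    m = np.maximum(2, np.round(m)).astype(int)

    # sampling effort and per-cell assemblages -------------------------------
    e0, e1 = cfg.effort_range
    if e0 == e1:
        efforts = np.full(cfg.n_cells, e0)
    else:
        efforts = np.exp(rng.uniform(np.log(e0), np.log(e1), cfg.n_cells))
        efforts = np.round(efforts).astype(int)

    alpha_cache: dict[int, float] = {}

    def cell_alpha(target: int) -> float:
        if target not in alpha_cache:
            alpha_cache[target] = _alpha_for_target(target, cfg.reference_effort)
        return alpha_cache[target]

    records: list[OccurrenceRecord] = []
    rec_id = 0
    for i, key in enumerate(keys):
        lat0, lon0 = positions[i]
        n_c = int(efforts[i])
        alpha = cell_alpha(int(m[i]))
        draws = np.empty(n_c, dtype=np.int64)
        if scenario in ("direct_environment", "null_flat"):
            pool = pools["global"]
            if scenario == "null_flat":
                pool = rng.permutation(pool)   # random turnover between cells
            ranks = _hoppe_urn(n_c, alpha, rng)
            draws[:] = pool[ranks % pool.size]
        else:
            w = weights.iloc[i].to_numpy()
            present = np.where(w > 0)[0]
            if present.size == 1:
                pool = pools[f"province{present[0] + 1}"]
                ranks = _hoppe_urn(n_c, alpha, rng)
                draws[:] = pool[ranks % pool.size]
            else:
                # split individuals between adjacent pools, one urn per pool
                assign = rng.choice(present, size=n_c, p=w[present])
                for k in present:
                    idx = np.where(assign == k)[0]
                    if idx.size == 0:
                        continue
                    pool = pools[f"province{k + 1}"]
                    ranks = _hoppe_urn(idx.size, alpha, rng)
                    draws[idx] = pool[ranks % pool.size]
        lat_j = lat0 + 0.25 + rng.uniform(-0.2, 0.2, efforts[i])
        lon_j = lon0 + 0.25 + rng.uniform(-0.2, 0.2, efforts[i])
        dps = rng.integers(2, 5, efforts[i])
        for s, la, lo_, dp in zip(draws, lat_j, lon_j, dps):
            records.append(
                OccurrenceRecord(
                    taxon_name=_species_name(int(s)),
                    latitude=round(la, int(dp)),
                    longitude=round(lo_, int(dp)),
                    source_id=f"synth-{rec_id}",
                    lat_text=_format_coord(la, int(dp)),
                    lon_text=_format_coord(lo_, int(dp)),
                )
            )
            rec_id += 1
    n_clean = len(records)

    # record-level noise: extra corrupted records ----------------------------
    f1, f2 = cfg.frac_missing_epithet, cfg.frac_low_precision
    f = f1 + f2
    n_noise = int(round(f * n_clean / (1.0 - f))) if f > 0 else 0
    n_drop = int(round(n_noise * (f1 / f))) if f > 0 else 0
    templates = rng.choice(n_clean, size=n_noise, replace=True) if n_noise else []
    for j, ti in enumerate(templates):
        base = records[int(ti)]
        if j < n_drop:   # genus-only name
            rec = OccurrenceRecord(
                taxon_name=base.taxon_name.split()[0],
                latitude=base.latitude,
                longitude=base.longitude,
                source_id=f"synth-noise-{j}",
                lat_text=base.lat_text,
                lon_text=base.lon_text,
            )
        else:            # coordinates stated to one decimal place
            rec = OccurrenceRecord(
                taxon_name=base.taxon_name,
                latitude=round(base.latitude, 1),
                longitude=round(base.longitude, 1),
                source_id=f"synth-noise-{j}",
                lat_text=_format_coord(base.latitude, 1),
                lon_text=_format_coord(base.longitude, 1),
            )
        records.append(rec)
    # shuffle record order so noise is interleaved, reproducibly
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    pool_names = {
        prov: [_species_name(int(s)) for s in idx] for prov, idx in pools.items()
    }
    truth = SynthTruth(
        labels=pd.Series(labels, index=pd.Index(keys, name="cell_id")),
        pools=pool_names,
        target_richness=pd.Series(m, index=pd.Index(keys, name="cell_id")),
        scenario=scenario,
        n_clean_records=n_clean,
        n_noise_records=n_noise,
        mixture=weights.set_index(pd.Index(keys, name="cell_id")),
        config=asdict(cfg),
    )
    return SynthWorld(records=records, env=env, truth=truth)


def generate_scenario(name: str, config: Optional[SynthConfig] = None) -> SynthWorld:
    """Generate a named hypothesis scenario (see module docstring)."""
    return generate_world(config, scenario=name)
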
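"""Diet-quality metric scoring: GDQS (with app-style cube quantization), MDDW,
AHEI-2010, GDR, and the 0-100 sodium screener.

GDQS category intervals are half-open ``[lower, upper)`` with the last
interval unbounded, so grams exactly at a cut-off fall in the upper category —
the same convention as the MDDW "met or exceeded 15 g" rule.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"
UNHEALTHY_IN_EXCESS = "unhealthy_in_excess"
CATEGORIES = (HEALTHY, UNHEALTHY, UNHEALTHY_IN_EXCESS)


def _data_path(name: str) -> Path:
    return Path(resources.files("dietmetrics").joinpath("data", name))


class ConfigError(ValueError):
    """A scoring configuration file violates its invariants."""


# ---------------------------------------------------------------------------
# Cube portion model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CubeSet:
    """The app's discrete portion-model geometry.

    A reported portion is the representable volume (a sum of cubes, each cube
    used at most ``max_multiplicity`` times) nearest to the true volume; the
    group's density converts between grams and millilitres.
    """

    volumes_ml: tuple[float, ...]
    density_g_per_ml: Mapping[str, float] = field(default_factory=dict)
    max_multiplicity: int = 2
    default_density: float | None = 1.0

    def __post_init__(self):
        v = np.asarray(self.volumes_ml, dtype=float)
        if len(v) == 0 or np.any(np.diff(v) <= 0) or np.any(v <= 0):
            raise ConfigError("cube volumes must be positive and strictly increasing")
        if any(d <= 0 for d in self.density_g_per_ml.values()):
            raise ConfigError("densities must be > 0")
        if self.max_multiplicity < 1:
            raise ConfigError("max_multiplicity must be >= 1")

    def density(self, group_id: str) -> float:
        if group_id in self.density_g_per_ml:
            return self.density_g_per_ml[group_id]
        if self.default_density is not None:
            return self.default_density
        raise ConfigError(f"no density configured for group {group_id!r}")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "CubeSet":
        with open(path or _data_path("cubes.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            volumes_ml=tuple(float(v) for v in cfg["volumes_ml"]),
            density_g_per_ml=dict(cfg.get("density_g_per_ml", {})),
            max_multiplicity=int(cfg.get("max_multiplicity", 2)),
            default_density=cfg.get("default_density_g_per_ml"),
        )


@functools.lru_cache(maxsize=32)
def representable_volumes(volumes_ml: tuple[float, ...], max_multiplicity: int) -> np.ndarray:
    """All volumes representable as a sum of cubes (each used <= max_multiplicity
    times), sorted ascending. 0 is always representable (no cubes)."""
    sums = np.array([0.0])
    for v in volumes_ml:
        sums = np.unique(
            np.concatenate([sums + k * v for k in range(max_multiplicity + 1)])
        )
    return sums


def quantize_with_cubes(true_grams: float, group_id: str, cube_set: CubeSet) -> float:
    """Snap a true gram amount to the nearest cube-representable amount.

    Ties between two equally near representable volumes break toward the
    smaller volume.
    """
    if true_grams < 0 or not np.isfinite(true_grams):
        raise ValueError("true_grams must be finite and >= 0")
    rho = cube_set.density(group_id)
    reps = representable_volumes(cube_set.volumes_ml, cube_set.max_multiplicity)
    vol = true_grams / rho
    i = int(np.searchsorted(reps, vol))
    if i == 0:
        return float(reps[0] * rho)
    if i == len(reps):
        return float(reps[-1] * rho)
    lo, hi = reps[i - 1], reps[i]
    v_star = lo if (vol - lo) <= (hi - vol) else hi  # tie -> smaller
    return float(v_star * rho)


def quantize_group_intakes(group_intakes: pd.DataFrame, cube_set: CubeSet) -> pd.DataFrame:
    """Apply :func:`quantize_with_cubes` to every row of a group-intake table."""
    out = group_intakes.copy()
    out["grams"] = [
        quantize_with_cubes(g, gid, cube_set)
        for g, gid in zip(out["grams"], out["group_id"])
    ]
    return out


# ---------------------------------------------------------------------------
# GDQS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GDQSGroup:
    group_id: str
    category: str
    cutoffs_g: tuple[float, ...]     # strictly increasing, 2 or 3 entries
    points: tuple[float, ...]        # len(cutoffs) + 1

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigError(f"{self.group_id}: unknown category {self.category!r}")
        c = np.asarray(self.cutoffs_g)
        if np.any(np.diff(c) <= 0) or np.any(c <= 0):
            raise ConfigError(f"{self.group_id}: cutoffs must be positive, strictly increasing")
        if len(self.points) != len(self.cutoffs_g) + 1:
            raise ConfigError(f"{self.group_id}: need len(cutoffs)+1 points")
        if any(p < 0 for p in self.points):
            raise ConfigError(f"{self.group_id}: points must be >= 0")

    def score(self, grams: float) -> float:
        """Points for a gram amount; boundary grams fall in the upper category."""
        return self.points[int(np.searchsorted(self.cutoffs_g, grams, side="right"))]


@dataclass(frozen=True)
class GDQSScoreTable:
    """Per-group GDQS categories, cut-offs, and points."""

    groups: Mapping[str, GDQSGroup]

    @property
    def max_score(self) -> float:
        return sum(max(g.points) for g in self.groups.values())

    @classmethod
    def from_csv(cls, path: str | Path | None = None) -> "GDQSScoreTable":
        df = pd.read_csv(path or _data_path("gdqs_table.csv"))
        groups = {}
        for _, row in df.iterrows():
            cutoffs = tuple(
                float(row[c]) for c in ("cutoff1", "cutoff2", "cutoff3")
                if c in row and pd.notna(row[c])
            )
            points = tuple(
                float(row[c]) for c in ("pts0", "pts1", "pts2", "pts3")
                if c in row and pd.notna(row[c])
            )
            groups[row["group_id"]] = GDQSGroup(
                group_id=row["group_id"], category=row["category"],
                cutoffs_g=cutoffs, points=points,
            )
        table = cls(groups=groups)
        import logging
        logging.getLogger("dietmetrics").info(
            "GDQS table: %d groups, max score %g", len(groups), table.max_score)
        return table

    @classmethod
    def toy(cls) -> "GDQSScoreTable":
        """Tiny three-group table used throughout the unit tests."""
        return cls(groups={
            "H": GDQSGroup("H", HEALTHY, (10, 40), (0, 1, 2)),
            "U": GDQSGroup("U", UNHEALTHY, (8, 30), (2, 1, 0)),
            "UE": GDQSGroup("UE", UNHEALTHY_IN_EXCESS, (5, 30, 100), (0, 1, 2, 0)),
        })


def score_gdqs(group_intakes: pd.DataFrame, table: GDQSScoreTable) -> pd.DataFrame:
    """GDQS totals and healthy/unhealthy submetrics per (participant, instrument).

    Every group in the score table contributes; a group absent from the intake
    table is scored at 0 g (which for unhealthy groups earns full points).
    Groups present in the intake but absent from the table are an error.
    """
    extra = set(group_intakes["group_id"]) - set(table.groups)
    if extra:
        raise ConfigError(f"groups not in GDQS score table: {sorted(extra)}")
    keys = group_intakes[["participant_id", "instrument"]].drop_duplicates()
    wide = (
        group_intakes.pivot_table(index=["participant_id", "instrument"],
                                  columns="group_id", values="grams",
                                  aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(table.groups), fill_value=0.0)
        .reindex(pd.MultiIndex.from_frame(keys), fill_value=0.0)
    )
    plus = np.zeros(len(wide))
    minus = np.zeros(len(wide))
    for gid, g in table.groups.items():
        pts = np.asarray(g.points, dtype=float)[
            np.searchsorted(g.cutoffs_g, wide[gid].to_numpy(), side="right")
        ]
        if g.category == HEALTHY:
            plus += pts
        else:
            minus += pts
    out = pd.DataFrame({
        "gdqs_plus": plus, "gdqs_minus": minus, "gdqs_total": plus + minus,
    }, index=wide.index)
    return out.reset_index()


# ---------------------------------------------------------------------------
# MDDW
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MDDWConfig:
    groups: Mapping[str, tuple[str, ...]]   # MDDW group -> member taxonomy groups
    threshold_g: float = 15.0
    min_groups: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "MDDWConfig":
        with open(path or _data_path("mddw.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            groups={k: tuple(v) for k, v in cfg["groups"].items()},
            threshold_g=float(cfg.get("threshold_g", 15.0)),
            min_groups=int(cfg.get("min_groups", 5)),
        )


def score_mddw(group_intakes: pd.DataFrame, config: MDDWConfig) -> pd.DataFrame:
    """MDDW diversity count (0-10) and the >=5-group adequacy indicator.

    An MDDW group is "consumed" when its member groups' summed grams meet or
    exceed the 15 g threshold; missing groups count as 0 g.
    """
    member_to_mddw = {
        m: mg for mg, members in config.groups.items() for m in members
    }
    gi = group_intakes.copy()
    gi["mddw_group"] = gi["group_id"].map(member_to_mddw)
    gi = gi.dropna(subset=["mddw_group"])
    sums = gi.groupby(["participant_id", "instrument", "mddw_group"])["grams"].sum()
    consumed = (sums >= config.threshold_g).groupby(["participant_id", "instrument"]).sum()
    keys = group_intakes[["participant_id", "instrument"]].drop_duplicates()
    counts = consumed.reindex(pd.MultiIndex.from_frame(keys), fill_value=0).astype(int)
    out = pd.DataFrame({
        "mddw_count": counts,
        "mddw_met": counts >= config.min_groups,
    })
    return out.reset_index()


# ---------------------------------------------------------------------------
# AHEI-2010
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AHEIComponent:
    name: str
    groups: tuple[str, ...]
    g_per_serving: float
    anchor0: float       # intake earning 0 points
    anchor10: float      # intake earning 10 points

    def score(self, servings: np.ndarray) -> np.ndarray:
        frac = (servings - self.anchor0) / (self.anchor10 - self.anchor0)
        return np.clip(10.0 * frac, 0.0, 10.0)


@dataclass(frozen=True)
class AHEIConfig:
    components: tuple[AHEIComponent, ...]
    sodium_from_screener: bool = True
    allow_partial_total: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "AHEIConfig":
        with open(path or _data_path("ahei.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        comps = tuple(
            AHEIComponent(
                name=name, groups=tuple(c["groups"]),
                g_per_serving=float(c["g_per_serving"]),
                anchor0=float(c["anchor0"]), anchor10=float(c["anchor10"]),
            )
            for name, c in cfg["components"].items()
        )
        for c in comps:
            if c.anchor0 == c.anchor10:
                raise ConfigError(f"AHEI component {c.name}: identical anchors")
        return cls(
            components=comps,
            sodium_from_screener=bool(cfg.get("sodium_from_screener", True)),
            allow_partial_total=bool(cfg.get("allow_partial_total", False)),
        )


def sodium_component_from_screener(screener_score: float | np.ndarray) -> np.ndarray:
    """AHEI sodium component proxied by the 0-100 screener: 10 * (1 - score/100)."""
    return np.clip(10.0 * (1.0 - np.asarray(screener_score, dtype=float) / 100.0), 0.0, 10.0)


def score_ahei(
    group_intakes: pd.DataFrame,
    config: AHEIConfig,
    sodium_screener: pd.Series | None = None,
) -> pd.DataFrame:
    """AHEI-2010 component and total scores per (participant, instrument).

    *sodium_screener* is a per-participant 0-100 score; required when the
    config proxies the sodium component through the screener.  A participant
    missing the screener gets a missing sodium component and (unless
    ``allow_partial_total``) a missing total.
    """
    keys = group_intakes[["participant_id", "instrument"]].drop_duplicates()
    idx = pd.MultiIndex.from_frame(keys)
    wide = (
        group_intakes.pivot_table(index=["participant_id", "instrument"],
                                  columns="group_id", values="grams",
                                  aggfunc="sum", fill_value=0.0)
        .reindex(idx, fill_value=0.0)
    )
    out = pd.DataFrame(index=idx)
    for comp in config.components:
        present = [g for g in comp.groups if g in wide.columns]
        grams = wide[present].sum(axis=1) if present else pd.Series(0.0, index=idx)
        out[f"ahei_{comp.name}"] = comp.score((grams / comp.g_per_serving).to_numpy())
    if config.sodium_from_screener:
        if sodium_screener is None:
            raise ConfigError("sodium_from_screener=True but no screener scores supplied")
        scr = idx.get_level_values("participant_id").map(sodium_screener)
        out["ahei_sodium"] = sodium_component_from_screener(scr.to_numpy(dtype=float))
    comp_cols = [c for c in out.columns if c.startswith("ahei_")]
    if config.allow_partial_total:
        out["ahei_total"] = out[comp_cols].sum(axis=1, min_count=1)
    else:
        out["ahei_total"] = out[comp_cols].sum(axis=1, skipna=False)
    return out.reset_index()


# ---------------------------------------------------------------------------
# GDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GDRConfig:
    encouraged: tuple[str, ...]
    limit: tuple[str, ...]

    def __post_init__(self):
        overlap = set(self.encouraged) & set(self.limit)
        if overlap:
            raise ConfigError(f"groups in both encouraged and limit lists: {sorted(overlap)}")

    @property
    def max_score(self) -> int:
        return len(self.encouraged) + len(self.limit)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "GDRConfig":
        with open(path or _data_path("gdr.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        return cls(encouraged=tuple(cfg["encouraged"]), limit=tuple(cfg["limit"]))


def score_gdr(group_intakes: pd.DataFrame, config: GDRConfig) -> pd.DataFrame:
    """GDR via the sentinel-food approach: a group is consumed if grams > 0.

    ``gdr_total = (# encouraged consumed) + (# limit NOT consumed)``,
    range 0 to len(encouraged) + len(limit).
    """
    keys = group_intakes[["participant_id", "instrument"]].drop_duplicates()
    idx = pd.MultiIndex.from_frame(keys)
    wide = (
        group_intakes.pivot_table(index=["participant_id", "instrument"],
                                  columns="group_id", values="grams",
                                  aggfunc="sum", fill_value=0.0)
        .reindex(idx, fill_value=0.0)
    )
    def consumed(groups: Sequence[str]) -> pd.Series:
        present = [g for g in groups if g in wide.columns]
        if not present:
            return pd.Series(0, index=idx)
        return (wide[present] > 0).sum(axis=1)
    enc = consumed(config.encouraged)
    lim = consumed(config.limit)
    out = pd.DataFrame({"gdr_total": enc + (len(config.limit) - lim)}, index=idx)
    return out.reset_index()


# ---------------------------------------------------------------------------
# Sodium screener
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenerConfig:
    items: Mapping[str, tuple[int, float]]   # item -> (max_level, weight)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ScreenerConfig":
        with open(path or _data_path("screener.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        return cls(items={
            name: (int(spec["max_level"]), float(spec.get("weight", 1.0)))
            for name, spec in cfg["items"].items()
        })


def score_sodium_screener(responses: pd.DataFrame, config: ScreenerConfig) -> pd.Series:
    """0-100 sodium-intake score from ordinal item responses.

    ``score = 100 * sum(w_i * x_i) / sum(w_i * max_i)``: all-minimum responses
    map to 0 and all-maximum to 100.  A response outside ``[0, max_level]``
    raises with the offending participant and item named.
    """
    missing = set(config.items) - set(responses.columns)
    if missing:
        raise ConfigError(f"screener responses missing items: {sorted(missing)}")
    raw = pd.Series(0.0, index=responses.index)
    denom = 0.0
    for item, (max_level, w) in config.items.items():
        x = responses[item].astype(float)
        bad = x[(x < 0) | (x > max_level) | (x != x.round())]
        if len(bad):
            raise ValueError(
                f"screener item {item!r}: out-of-range responses for "
                f"{bad.index.tolist()[:5]}"
            )
        raw += w * x
        denom += w * max_level
    return 100.0 * raw / denom


# ---------------------------------------------------------------------------
# Convenience: all metrics for one instrument pathway
# ---------------------------------------------------------------------------

def metric_sd_units(metrics: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
    """Sample SDs used for per-SD effect scaling, one per metric column."""
    return metrics[list(columns)].std(ddof=1)
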
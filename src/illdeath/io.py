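"""CSV readers/writers and run-configuration validation.

The on-disk dialect is fixed: comma-separated, dot decimal, UTF-8,
mandatory header.  Curve tables carry two columns, ``age`` plus a
value column (``value``, ``p``, ``i`` or ``rate``), ages strictly
increasing.  Numbers are written with 12 significant digits so a
write/read round trip is lossless at the accuracy the solvers deliver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .errors import ParseError, ValidationError
from .rates import AgeDomain, MortalityInput, MortalityTag, RateFunction

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "parse_rate_spec",
    "RunConfig",
    "validate_config",
]

log = logging.getLogger("illdeath")

_VALUE_HEADERS = {"value", "p", "i", "i_hat", "rate"}
_FLOAT_FMT = "%.12g"


def read_curve_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read an ``age,value`` table; returns ``(ages, values)`` arrays.

    Ages must be strictly increasing (duplicates are an error) and all
    cells numeric; errors name the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if len(header) != 2 or header[0] != "age" or header[1] not in _VALUE_HEADERS:
        raise ParseError(
            f"{path}: line 1: expected header 'age,value' (or age,p), got {lines[0]!r}"
        )
    ages, values = [], []
    for k, ln in enumerate(lines[1:], start=2):
        cells = ln.split(",")
        if len(cells) != 2:
            raise ParseError(f"{path}: line {k}: expected 2 columns, got {len(cells)}")
        try:
            a, v = float(cells[0]), float(cells[1])
        except ValueError:
            raise ParseError(f"{path}: line {k}: non-numeric cell in {ln!r}") from None
        if not (np.isfinite(a) and np.isfinite(v)):
            raise ParseError(f"{path}: line {k}: non-finite value")
        ages.append(a)
        values.append(v)
    if not ages:
        raise ParseError(f"{path}: no data rows")
    ages_arr = np.asarray(ages)
    if np.any(np.diff(ages_arr) <= 0):
        k = int(np.argmax(np.diff(ages_arr) <= 0)) + 3  # 1 header + 1-based + next row
        raise ParseError(f"{path}: line {k}: ages not strictly increasing")
    return ages_arr, np.asarray(values)


def write_curve_csv(path, ages, values, value_header: str = "value") -> None:
    """Write an ``age,<value_header>`` table (12 significant digits)."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"age,{value_header}\n")
        for a, v in zip(ages, values):
            fh.write(f"{_FLOAT_FMT % a},{_FLOAT_FMT % v}\n")


def parse_rate_spec(spec, domain: AgeDomain, name: str = "rate") -> RateFunction:
    """Build a :class:`RateFunction` from a CLI/config specification.

    Accepted forms:

    - ``"gompertz:<beta0>,<beta1>"`` or ``{"beta0": .., "beta1": ..}``
    - ``"const:<value>"`` or a bare number (age-independent rate)
    - a path to an ``age,value`` CSV (tabulated, linear interpolation)
    """
    if isinstance(spec, RateFunction):
        return spec
    if isinstance(spec, dict):
        try:
            return RateFunction.gompertz(spec["beta0"], spec["beta1"], domain)
        except KeyError:
            raise ValidationError(
                f"{name}: mapping spec needs keys beta0 and beta1, got {spec}"
            ) from None
    if isinstance(spec, (int, float)):
        return RateFunction.constant(float(spec), domain)
    if isinstance(spec, str):
        s = spec.strip()
        if s.startswith("gompertz:"):
            try:
                b0, b1 = (float(x) for x in s[len("gompertz:"):].split(","))
            except ValueError:
                raise ValidationError(
                    f"{name}: expected gompertz:<beta0>,<beta1>, got {spec!r}"
                ) from None
            return RateFunction.gompertz(b0, b1, domain)
        if s.startswith("const:"):
            try:
                return RateFunction.constant(float(s[len("const:"):]), domain)
            except ValueError:
                raise ValidationError(f"{name}: bad constant in {spec!r}") from None
        try:
            return RateFunction.constant(float(s), domain)
        except ValueError:
            pass
        ages, values = read_curve_csv(s)
        rf = RateFunction.from_table(ages, values, step=domain.step)
        if rf.domain.a0 > domain.a0 + 1e-9 or rf.domain.omega < domain.omega - 1e-9:
            raise ValidationError(
                f"{name}: table {s} covers [{rf.domain.a0}, {rf.domain.omega}], "
                f"run domain is [{domain.a0}, {domain.omega}]"
            )
        return rf
    raise ValidationError(f"{name}: cannot interpret rate spec {spec!r}")


@dataclass
class RunConfig:
    """Fully resolved settings for one CLI run."""

    subcommand: str
    domain: AgeDomain
    incidence: Optional[RateFunction] = None
    mortality: Optional[MortalityInput] = None
    p0: float = 0.0
    s0: float = 1.0
    c0: float = 0.0
    n0: int = 100_000
    seed: Optional[int] = None
    relative_risks: tuple = ()
    derivative_method: str = "central_difference"
    smoothing: Optional[float] = None
    rtol: float = 1e-10
    atol: float = 1e-12
    prevalence_path: Optional[str] = None
    out: Optional[str] = None
    extra: dict = field(default_factory=dict)


_TAG_ALIASES = {t.value: t for t in MortalityTag}
_TAG_ALIASES.update({t.name: t for t in MortalityTag})


def _resolve_tag(raw) -> MortalityTag:
    key = str(raw).strip()
    for cand in (key, key.lower(), key.upper()):
        if cand in _TAG_ALIASES:
            return _TAG_ALIASES[cand]
    raise ValidationError(
        f"unknown mortality tag {raw!r}; choose from "
        f"{sorted(t.value for t in MortalityTag)}"
    )


def build_mortality(
    tag_raw,
    domain: AgeDomain,
    m=None,
    m0=None,
    m1=None,
    relative_risk=None,
) -> MortalityInput:
    """Assemble a :class:`MortalityInput`, checking that exactly the two
    components the tag requires were given."""
    tag = _resolve_tag(tag_raw)
    given = {
        "m": m,
        "m0": m0,
        "m1": m1,
        "R": relative_risk,
    }
    need = tag.component_names
    missing = [n for n in need if given[n] is None]
    if missing:
        raise ValidationError(
            f"tag {tag.value!r} requires {need}; missing: {', '.join(missing)}"
        )
    surplus = [n for n, v in given.items() if v is not None and n not in need]
    if surplus:
        raise ValidationError(
            f"tag {tag.value!r} requires only {need}; unexpected: {', '.join(surplus)}"
        )
    first = parse_rate_spec(given[need[0]], domain, name=need[0])
    second = parse_rate_spec(given[need[1]], domain, name=need[1])
    return MortalityInput(tag, first, second)


def validate_config(raw: dict) -> RunConfig:
    """Resolve a raw mapping (config file merged with CLI flags) into a
    :class:`RunConfig` with defaults applied, and log the effective
    settings."""
    raw = dict(raw)
    sub = raw.pop("subcommand", None)
    if sub is None:
        raise ValidationError("config needs a 'subcommand'")
    domain = AgeDomain(
        float(raw.pop("a0", 0.0)),
        float(raw.pop("omega", 100.0)),
        float(raw.pop("step", 0.1)),
    )
    cfg = RunConfig(subcommand=sub, domain=domain)
    if "incidence" in raw:
        cfg.incidence = parse_rate_spec(raw.pop("incidence"), domain, "incidence")
    if "tag" in raw:
        cfg.mortality = build_mortality(
            raw.pop("tag"),
            domain,
            m=raw.pop("m", None),
            m0=raw.pop("m0", None),
            m1=raw.pop("m1", None),
            relative_risk=raw.pop("relative_risk", None),
        )
    else:
        for key in ("m", "m0", "m1", "relative_risk"):
            raw.pop(key, None)
    cfg.p0 = float(raw.pop("p0", 0.0))
    if not (0.0 <= cfg.p0 <= 1.0):
        raise ValidationError(f"p0 must lie in [0, 1], got {cfg.p0}")
    cfg.s0 = float(raw.pop("s0", 1.0))
    cfg.c0 = float(raw.pop("c0", 0.0))
    cfg.n0 = int(raw.pop("n0", 100_000))
    seed = raw.pop("seed", None)
    cfg.seed = None if seed is None else int(seed)
    rr = raw.pop("relative_risks", ())
    if isinstance(rr, str):
        rr = [float(x) for x in rr.split(",") if x.strip()]
    cfg.relative_risks = tuple(float(x) for x in rr)
    cfg.derivative_method = str(raw.pop("derivative", "central_difference"))
    sm = raw.pop("smoothing", None)
    cfg.smoothing = None if sm is None else float(sm)
    cfg.rtol = float(raw.pop("rtol", 1e-10))
    cfg.atol = float(raw.pop("atol", 1e-12))
    cfg.prevalence_path = raw.pop("prevalence", None)
    cfg.out = raw.pop("out", None)
    cfg.extra = raw
    log.info("effective config: %s", cfg)
    return cfg


def load_config_file(path) -> dict:
    """Load a flat YAML/JSON mapping of run settings."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data
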
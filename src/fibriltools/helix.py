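"""Helical-parameter geometry: rise, twist, pitch, crossover, handedness.

A helical fibril advances by a rise (Å) and rotates by a twist (degrees)
per subunit. One full 360° turn therefore spans a pitch of
rise × 360/|twist|. In projection a ribbon-like fibril shows an apparent
width minimum ("crossover") twice per turn, so crossover = pitch / 2 by
default; the number of crossovers per turn is configurable for other
morphologies. Negative twist means a left-handed helix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .traces import InvalidParameterError

__all__ = [
    "HelicalParams",
    "pitch_from_rise_twist",
    "crossover_from_pitch",
    "pitch_from_crossover",
    "twist_from_crossover",
    "consistency_report",
]


def pitch_from_rise_twist(rise_A: float, twist_deg: float) -> float:
    """Pitch in nm from rise (Å/subunit) and twist (deg/subunit)."""
    if rise_A <= 0:
        raise InvalidParameterError("rise must be positive")
    if twist_deg == 0:
        raise InvalidParameterError("pitch is undefined for zero twist")
    return rise_A * (360.0 / abs(twist_deg)) / 10.0


def crossover_from_pitch(pitch_nm: float, crossovers_per_turn: int = 2) -> float:
    """Crossover spacing in nm (default: two crossovers per 360° turn)."""
    if pitch_nm <= 0:
        raise InvalidParameterError("pitch must be positive")
    if crossovers_per_turn < 1:
        raise InvalidParameterError("crossovers_per_turn must be >= 1")
    return pitch_nm / crossovers_per_turn


def pitch_from_crossover(crossover_nm: float, crossovers_per_turn: int = 2) -> float:
    """Inverse of :func:`crossover_from_pitch`."""
    if crossover_nm <= 0:
        raise InvalidParameterError("crossover must be positive")
    if crossovers_per_turn < 1:
        raise InvalidParameterError("crossovers_per_turn must be >= 1")
    return crossover_nm * crossovers_per_turn


def twist_from_crossover(
    rise_A: float,
    crossover_nm: float,
    handedness: str = "left",
    crossovers_per_turn: int = 2,
) -> float:
    """Twist (deg/subunit, signed) implied by a measured crossover spacing.

    |twist| = rise × (360 / crossovers_per_turn) / (10 × crossover);
    left-handed helices get a negative sign.
    """
    if rise_A <= 0:
        raise InvalidParameterError("rise must be positive")
    if crossover_nm <= 0:
        raise InvalidParameterError("crossover must be positive")
    if handedness not in ("left", "right"):
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    pitch_nm = pitch_from_crossover(crossover_nm, crossovers_per_turn)
    magnitude = rise_A * 360.0 / (pitch_nm * 10.0)
    return -magnitude if handedness == "left" else magnitude


@dataclass
class HelicalParams:
    """Partially specified helical parameters; None = not measured.

    Invariant (checked by :func:`consistency_report`): when more than one
    route to the pitch is available, they must agree within tolerance.
    """

    rise_A: float | None = None
    twist_deg: float | None = None
    pitch_nm: float | None = None
    crossover_nm: float | None = None

    @property
    def handedness(self) -> str | None:
        if self.twist_deg is None:
            return None
        return "left" if self.twist_deg < 0 else "right"


def consistency_report(
    params: HelicalParams,
    tolerance_frac: float = 0.10,
    crossovers_per_turn: int = 2,
) -> dict:
    """Fill derivable helical parameters and cross-check the provided ones.

    Pitch estimates are collected from every available route (given
    directly; rise+twist; crossover); missing fields are filled from the
    first available route. Every provided quantity is compared against
    its value implied by the other routes; relative discrepancies above
    ``tolerance_frac`` are flagged.

    Raises
    ------
    ValueError
        If fewer than two independent pitch routes and fewer than two set
        fields are available (nothing to check or derive from).
    """
    pitch_routes: dict[str, float] = {}
    if params.pitch_nm is not None:
        pitch_routes["pitch"] = params.pitch_nm
    if params.rise_A is not None and params.twist_deg is not None:
        pitch_routes["rise+twist"] = pitch_from_rise_twist(params.rise_A, params.twist_deg)
    if params.crossover_nm is not None:
        pitch_routes["crossover"] = pitch_from_crossover(
            params.crossover_nm, crossovers_per_turn
        )

    n_set = sum(
        v is not None
        for v in (params.rise_A, params.twist_deg, params.pitch_nm, params.crossover_nm)
    )
    if n_set < 2:
        missing = [
            name
            for name, v in (
                ("rise_A", params.rise_A),
                ("twist_deg", params.twist_deg),
                ("pitch_nm", params.pitch_nm),
                ("crossover_nm", params.crossover_nm),
            )
            if v is None
        ]
        raise ValueError(
            "under-specified helical parameters: need at least two of "
            f"rise/twist/pitch/crossover; missing {missing}"
        )
    if not pitch_routes:
        raise ValueError(
            "cannot derive a pitch: supply pitch, crossover, or both rise and twist"
        )

    # Fill derivable fields from the first available route.
    route_order = ("pitch", "rise+twist", "crossover")
    ref_pitch = next(pitch_routes[r] for r in route_order if r in pitch_routes)
    implied = {
        "pitch_nm": ref_pitch,
        "crossover_nm": crossover_from_pitch(ref_pitch, crossovers_per_turn),
    }
    if params.rise_A is not None:
        hand = params.handedness or "left"
        implied["twist_deg"] = twist_from_crossover(
            params.rise_A, implied["crossover_nm"], hand, crossovers_per_turn
        )
    if params.twist_deg is not None:
        implied["rise_A"] = abs(params.twist_deg) * ref_pitch * 10.0 / 360.0

    discrepancies = []
    names = list(pitch_routes)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = pitch_routes[names[i]], pitch_routes[names[j]]
            rel = abs(a - b) / min(abs(a), abs(b))
            discrepancies.append(
                {
                    "pair": (names[i], names[j]),
                    "pitch_nm": (a, b),
                    "relative_discrepancy": rel,
                    "flagged": rel > tolerance_frac,
                }
            )

    filled = HelicalParams(
        rise_A=params.rise_A if params.rise_A is not None else implied.get("rise_A"),
        twist_deg=params.twist_deg
        if params.twist_deg is not None
        else implied.get("twist_deg"),
        pitch_nm=params.pitch_nm if params.pitch_nm is not None else implied["pitch_nm"],
        crossover_nm=params.crossover_nm
        if params.crossover_nm is not None
        else implied["crossover_nm"],
    )
    return {
        "provided": params,
        "filled": filled,
        "implied": implied,
        "pitch_routes_nm": pitch_routes,
        "discrepancies": discrepancies,
        "any_flagged": any(d["flagged"] for d in discrepancies),
        "tolerance_frac": tolerance_frac,
        "crossovers_per_turn": crossovers_per_turn,
        "handedness": filled.handedness,
    }
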
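"""Class target values and their mapping constraints.

Binary regression-style classification maps the two classes to scalar
targets T_Adeno = 0.85 and T_Meso = 0.65.  On features normalized to [0,1]
each target must sit above the mean of its class's per-feature means, and a
separation constraint |T_Adeno − T_Meso| >= 0.5 is evaluated.  The chosen
targets differ by 0.2, so the separation check reports a violation by
construction; it is recorded, not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ADENO_TARGET_DEFAULT = 0.85
MESO_TARGET_DEFAULT = 0.65


@dataclass
class TargetMap:
    t_adeno: float = ADENO_TARGET_DEFAULT
    t_meso: float = MESO_TARGET_DEFAULT
    adeno_constraint_ok: bool = True
    meso_constraint_ok: bool = True
    separation_ok: bool = True
    warnings: list[str] = field(default_factory=list)

    def target_of(self, label: str) -> float:
        return self.t_adeno if label == "Adeno" else self.t_meso

    def target_vector(self, labels: np.ndarray) -> np.ndarray:
        return np.array([self.target_of(l) for l in labels], dtype=float)


def select_targets(
    adeno_features: np.ndarray,
    meso_features: np.ndarray,
    t_adeno: float = ADENO_TARGET_DEFAULT,
    t_meso: float = MESO_TARGET_DEFAULT,
) -> TargetMap:
    """Return the class targets and verify their mapping constraints.

    ``adeno_features`` / ``meso_features`` are feature x subject matrices
    normalized to [0,1].  The targets themselves are always returned; failed
    constraints attach warnings.
    """
    adeno_features = np.asarray(adeno_features, dtype=float)
    meso_features = np.asarray(meso_features, dtype=float)

    tm = TargetMap(t_adeno=t_adeno, t_meso=t_meso)

    mean_adeno = float(np.mean(adeno_features)) if adeno_features.size else 0.0
    mean_meso = float(np.mean(meso_features)) if meso_features.size else 0.0
    if mean_adeno > t_adeno:
        tm.adeno_constraint_ok = False
        tm.warnings.append(
            f"Adeno mapping constraint violated: mean of feature means "
            f"{mean_adeno:.4f} > T_Adeno {t_adeno}"
        )
    if mean_meso > t_meso:
        tm.meso_constraint_ok = False
        tm.warnings.append(
            f"Meso mapping constraint violated: mean of feature means "
            f"{mean_meso:.4f} > T_Meso {t_meso}"
        )
    if abs(t_adeno - t_meso) < 0.5:
        tm.separation_ok = False
        tm.warnings.append(
            f"target separation |{t_adeno} - {t_meso}| = "
            f"{abs(t_adeno - t_meso):.2f} < 0.5"
        )
    return tm
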
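"""The 22 evaluated model structures.

Each configuration toggles: data fusion (joint count + presence likelihood),
shared vs species-independent fixed effects, a purely spatial shared field, a
shared spatio-temporal field, species-specific spatio-temporal fields, and a
spatially varying coefficient (SVC) on the year trend.  The machine-readable
matrix below fixes the catalogue row for row, including the duplicated
M4/M5 rows of the original tabulation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

# Columns: fusion, joint, shared_fe, indep_fe, spatial, shared_st, species_st, svc
_TABLE1 = """model,data_fusion,joint_structure,shared_fixed_effects,independent_fixed_effects,spatial_only_effect,shared_st_effect,species_st_effects,svc_effect
M1,0,0,0,0,0,0,0,0
M2,0,0,1,0,1,0,0,0
M3,0,0,1,0,0,1,0,0
M4,0,1,1,0,0,1,0,0
M5,0,1,1,0,0,1,0,0
M6,0,1,1,0,0,0,1,0
M7,0,1,1,0,0,1,0,1
M8,0,1,1,0,0,0,1,1
M9,1,1,1,0,0,1,0,0
M10,1,1,1,0,0,0,1,0
M11,1,1,0,1,0,1,0,0
M12,1,1,0,1,0,0,1,0
M13,1,1,1,0,0,1,1,0
M14,1,1,0,1,0,1,1,0
M15,1,1,1,0,0,1,0,1
M16,1,1,1,0,0,0,1,1
M17,1,1,0,1,0,1,0,1
M18,1,1,0,1,0,0,1,1
M19,1,1,1,0,0,1,1,1
M20,1,1,0,1,0,1,1,1
M21,0,1,1,0,0,1,1,0
M22,0,1,0,1,0,1,1,0
"""


@dataclass(frozen=True)
class ModelConfig:
    """Structure switchboard for one model.

    Exactly one of ``shared_fixed_effects`` / ``independent_fixed_effects``
    is active once resolved; models listed with neither (the covariate-only
    baseline M1) default to shared estimation.
    """

    model_id: str = "custom"
    data_fusion: bool = False
    joint_structure: bool = False
    shared_fixed_effects: bool = True
    independent_fixed_effects: bool = False
    spatial_only_effect: bool = False
    shared_st_effect: bool = False
    species_st_effects: bool = False
    svc_effect: bool = False

    def __post_init__(self):
        if self.shared_fixed_effects and self.independent_fixed_effects:
            raise ValueError("fixed effects are either shared or independent,"
                             " not both")
        if not (self.shared_fixed_effects or self.independent_fixed_effects):
            raise ValueError("one fixed-effect estimation mode must be active")

    @property
    def has_random_effects(self) -> bool:
        return (self.spatial_only_effect or self.shared_st_effect
                or self.species_st_effects or self.svc_effect)


def table1() -> pd.DataFrame:
    """The model catalogue matrix as a DataFrame indexed by model id."""
    df = pd.read_csv(io.StringIO(_TABLE1), index_col="model")
    return df.astype(bool)


def make_configs() -> dict[str, ModelConfig]:
    """All 22 configurations, keyed M1..M22."""
    out = {}
    for mid, row in table1().iterrows():
        shared = bool(row["shared_fixed_effects"])
        indep = bool(row["independent_fixed_effects"])
        if not shared and not indep:
            shared = True  # covariate-only baseline: pooled estimation
        out[mid] = ModelConfig(
            model_id=mid,
            data_fusion=bool(row["data_fusion"]),
            joint_structure=bool(row["joint_structure"]),
            shared_fixed_effects=shared,
            independent_fixed_effects=indep,
            spatial_only_effect=bool(row["spatial_only_effect"]),
            shared_st_effect=bool(row["shared_st_effect"]),
            species_st_effects=bool(row["species_st_effects"]),
            svc_effect=bool(row["svc_effect"]),
        )
    return out


def get_config(model_id: str) -> ModelConfig:
    configs = make_configs()
    if model_id not in configs:
        raise ValueError(f"unknown model id {model_id!r}; expected M1..M22")
    return configs[model_id]
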
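"""Fitted-driver facade: one object bundling conductor, discretization,
solver and source-model factory, constructed from a configuration
dictionary.

    >>> driver = FittedDriver({
    ...     "type": "fitted",
    ...     "solver_type": "cg",
    ...     "element_type": "tetrahedron",
    ...     "volume_conductor": {
    ...         "grid.filename": "path/to/grid.msh",
    ...         "tensors.filename": "path/to/tensors.dat",
    ...     },
    ... })

Switching the discretization (cg -> dg) needs no other changes beyond
supplying the DG penalty parameter.
"""

from __future__ import annotations

import numpy as np

from . import io
from .config import ConfigError, DriverConfig, parse_config
from .eeg import Assembly, TransferMatrix, apply_transfer, compute_eeg_transfer, solve_eeg_forward
from .meg import CoilSet, MEGTransfer, compute_meg_transfer, solve_meg_forward
from .mesh import VolumeConductor


class FittedDriver:
    """Drives EEG/MEG forward solves for fitted (mesh-conforming) FEM."""

    def __init__(self, config: dict | DriverConfig,
                 volume_conductor: VolumeConductor | None = None):
        cfg = config if isinstance(config, DriverConfig) else parse_config(config)
        self.config = cfg
        if volume_conductor is None:
            if cfg.grid_filename is None or cfg.tensors_filename is None:
                raise ConfigError(
                    "volume_conductor.grid.filename and "
                    "volume_conductor.tensors.filename are required"
                )
            mesh = io.read_gmsh(cfg.grid_filename)
            if mesh.element_kind != cfg.element_type:
                raise ConfigError(
                    f"mesh contains {mesh.element_kind} elements but the "
                    f"configuration requests {cfg.element_type}"
                )
            volume_conductor = io.read_conductivities(cfg.tensors_filename, mesh)
        self.vc = volume_conductor
        self.assembly = Assembly(
            self.vc,
            scheme=cfg.solver_type,
            tol=cfg.tolerance,
            eta=cfg.penalty if cfg.penalty is not None else 4.0,
            preconditioner=cfg.preconditioner,
        )
        sm = dict(cfg.source_model)
        self._sm_name = sm.pop("type")
        self._sm_post = sm.pop("post_process", True)
        self._sm_params = sm
        self._model = None

    @property
    def source_model(self):
        if self._model is None:
            self._model = self.assembly.source_model(
                self._sm_name, post_process=self._sm_post, **self._sm_params
            )
        return self._model

    def solve_eeg_forward(self, dipoles, electrodes) -> np.ndarray:
        return solve_eeg_forward(
            self.vc, dipoles, electrodes, assembly=self.assembly,
            model=self.source_model,
        )

    def compute_eeg_transfer(self, electrodes) -> TransferMatrix:
        return compute_eeg_transfer(self.vc, electrodes, assembly=self.assembly)

    def apply_eeg_transfer(self, transfer: TransferMatrix, dipoles,
                           electrodes=None) -> np.ndarray:
        return apply_transfer(transfer, self.source_model, dipoles, electrodes)

    def compute_meg_transfer(self, coils: CoilSet) -> MEGTransfer:
        return compute_meg_transfer(self.vc, coils, self.assembly)

    def solve_meg_forward(self, dipoles, coils: CoilSet, **kwargs) -> np.ndarray:
        return solve_meg_forward(
            self.vc, dipoles, coils, assembly=self.assembly,
            source_model=self._sm_name, **kwargs,
        )
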
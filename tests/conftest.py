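"""Shared fixtures: small synthetic worlds built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from tesplan.cortex import make_sphere_mesh, parcellate_surface
from tesplan.fdm import assemble_fdm_system, lead_field_from_reciprocity
from tesplan.phantom import (
    DEFAULT_4SHELL,
    ShellSpec,
    build_shell_phantom,
    place_geodesic_electrodes,
)
from tesplan.targeting import MontageEvaluator


class World:
    """A phantom plus everything derived from it (system, electrodes, lead field)."""

    def __init__(self, spec, spacing_mm, n_electrodes, cortex_radius_mm, patch_area_cm2, subdivisions=3):
        self.spec = spec
        self.model = build_shell_phantom(spec, spacing_mm=spacing_mm)
        self.center = self.model._center_mm
        self.system = assemble_fdm_system(self.model)
        self.electrodes = place_geodesic_electrodes(self.model, n_electrodes)
        self.mesh = make_sphere_mesh(
            radius_mm=cortex_radius_mm, subdivisions=subdivisions, center_mm=tuple(self.center)
        )
        self.parcellation = parcellate_surface(self.mesh, patch_area_cm2)
        self.lfm, self.solutions = lead_field_from_reciprocity(
            self.system, self.electrodes, self.parcellation, tol=1e-8, return_solutions=True
        )
        self._evaluator = None

    @property
    def evaluator(self) -> MontageEvaluator:
        if self._evaluator is None:
            self._evaluator = MontageEvaluator(
                self.system, self.electrodes, self.parcellation, solutions=self.solutions
            )
        return self._evaluator


@pytest.fixture(scope="session")
def four_shell_world() -> World:
    """4-shell head at 4 mm with a dense geodesic array and ~1 cm^2 patches."""
    return World(DEFAULT_4SHELL, 4.0, 64, 70.0, 1.0)


@pytest.fixture(scope="session")
def homog_world() -> World:
    """Homogeneous conducting sphere at 4 mm (scalp-labeled throughout)."""
    return World(ShellSpec(((92.0, "scalp"),)), 4.0, 16, 60.0, 4.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
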
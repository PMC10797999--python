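import pytest

import tfscreen as tfs


@pytest.fixture(scope="session")
def factors():
    return tfs.default_screen_factors()


@pytest.fixture(scope="session")
def variants(factors):
    return tfs.build_fcccd(factors)


@pytest.fixture(scope="session")
def plan(variants, factors):
    return tfs.replicate_plan(variants, factors, central_reps=5, outer_reps=1,
                              bio_reps=2, seed=11)


@pytest.fixture(scope="session")
def design_df(variants, factors):
    return tfs.design_frame(variants, factors)


@pytest.fixture(scope="session")
def noisefree_surfaces():
    return tfs.default_control_surfaces(noise_cv=0.0)


@pytest.fixture(scope="session")
def noisefree_screen(plan, noisefree_surfaces):
    """Noise-free control + one strain per non-control archetype."""
    g, fl = noisefree_surfaces
    assign = {"control": tfs.StrainArchetype("control", g, fl)}
    for label in tfs.ARCHETYPE_LABELS:
        if label == "control":
            continue
        assign[f"tf_{label}"] = tfs.make_archetype(label, base_growth=g, base_fluorescence=fl)
    readouts, truth = tfs.simulate_screen(assign, plan, seed=21)
    fc = tfs.fold_change_table(readouts, plan, control="control")
    return readouts, truth, fc
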
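import pytest

import mcprobit as m


@pytest.fixture(scope="session")
def uniform_x_prior():
    return m.PriorSpec(kind="uniform", x_min=0.1, x_max=6.0)


@pytest.fixture(scope="session")
def continuous_spec():
    return m.VariableSpec(
        "w", "continuous", mean_spec="pow_law_offset", noise_spec="lin_pos_int", group="long"
    )


@pytest.fixture(scope="session")
def ordinal_spec():
    return m.VariableSpec(
        "v", "ordinal", M=3, mean_spec="pow_law", noise_spec="const", group="fuse"
    )


@pytest.fixture(scope="session")
def continuous_theta():
    return m.ThetaUnivariate(mean=(0.8, 30.0, 60.0), noise=(4.0, 0.1))


@pytest.fixture(scope="session")
def ordinal_theta():
    return m.ThetaUnivariate(mean=(0.7,), noise=(1.0,), tau=(0.5, 1.5, 2.5))


@pytest.fixture(scope="session")
def mixed_pair_dataset(continuous_spec, ordinal_spec, continuous_theta, ordinal_theta,
                       uniform_x_prior):
    """One ordinal + one continuous variable with residual correlation 0.6."""
    theta = m.ThetaMultivariate(
        thetas=(ordinal_theta, continuous_theta), z=(0.6,), grouping=("fuse", "long")
    )
    design = m.SimulationDesign(
        theta_true=theta,
        specs=(ordinal_spec, continuous_spec),
        x_distribution=uniform_x_prior,
        n=600,
        seed=42,
    )
    return m.simulate_dataset(design), theta


@pytest.fixture(scope="session")
def paper_fixture():
    return m.paper_like_fixture(seed=0, n=400)


@pytest.fixture(scope="session")
def four_variable_dataset():
    """Two continuous + two ordinal variables in three groups (J=4)."""
    specs = (
        m.VariableSpec("v1", "ordinal", M=2, mean_spec="lin", noise_spec="const", group="a"),
        m.VariableSpec("v2", "ordinal", M=3, mean_spec="pow_law", noise_spec="const", group="a"),
        m.VariableSpec("w1", "continuous", noise_spec="const", group="b"),
        m.VariableSpec("w2", "continuous", noise_spec="lin_pos_int", group="c"),
    )
    thetas = (
        m.ThetaUnivariate(mean=(), noise=(1.2,), tau=(1.0, 3.0)),
        m.ThetaUnivariate(mean=(0.8,), noise=(0.9,), tau=(0.5, 1.2, 2.2)),
        m.ThetaUnivariate(mean=(0.9, 10.0, 20.0), noise=(2.0,)),
        m.ThetaUnivariate(mean=(0.7, 5.0, 8.0), noise=(1.0, 0.2)),
    )
    # slots: within a; between (a,b), (a,c), (b,c)
    theta = m.ThetaMultivariate(thetas=thetas, z=(0.5, 0.3, -0.2, 0.4), grouping=("a", "a", "b", "c"))
    design = m.SimulationDesign(
        theta_true=theta,
        specs=specs,
        x_distribution=m.PriorSpec(kind="uniform", x_min=0.2, x_max=5.0),
        n=40,
        seed=3,
    )
    return m.simulate_dataset(design), theta
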
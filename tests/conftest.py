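import pytest

import enfetsim as es


@pytest.fixture
def glucose_device():
    """350-nm-node glucose-sensor device: Ag gate electrode, O- product,
    SiO2 (40 nm) + 1-mm aqueous enzymatic layer."""
    return es.Device(
        transistor=es.TransistorParams(W=0.5, L=0.035, mu_c=800.0, V_T_FET=1.5),
        gate_stack=es.GateStack(
            [
                es.InsulatorLayer(thickness=40e-7, rel_permittivity=3.9, label="SiO2"),
                es.InsulatorLayer(thickness=0.1, rel_permittivity=80.0, label="enzymatic"),
            ]
        ),
        electrochem=es.ElectroChem(V0=0.79, z_nernst=-2),
        helmholtz=es.HelmholtzModel(t_H=1e-5, z_q=-1),
        bias=es.BiasPoint(V_ext=2.0),
    )


@pytest.fixture
def glucose_device_config():
    """Same device as a config-file document (lengths in nm)."""
    return {
        "transistor": {
            "W_nm": 5e6,
            "L_nm": 3.5e5,
            "mu_c_cm2_per_Vs": 800.0,
            "V_T_FET_V": 1.5,
        },
        "gate_stack": [
            {"label": "SiO2", "thickness_nm": 40.0, "rel_permittivity": 3.9},
            {"label": "enzymatic", "thickness_nm": 1e6, "rel_permittivity": 80.0},
        ],
        "electrochem": {"V0_V": 0.79, "z_nernst": -2},
        "helmholtz": {"t_H_nm": 100.0, "z_q": -1},
        "bias": {"V_ext_V": 2.0},
    }


@pytest.fixture
def gox_params():
    """Glucose-oxidase Michaelis-Menten constants: K_M = 10 mM, v_max = 0.018 mol/(L s)."""
    return es.RateLawParams(v_max=0.018, K_M=0.01)
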
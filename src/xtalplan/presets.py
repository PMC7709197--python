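"""Published reference inputs for the lysozyme / NaCl / PEG 4000 system.

These are the fitted constants and crystal-form data for hen egg-white
lysozyme crystallized in 0.4 M NaCl, 15% PEG 4000, 0.04% sodium azide,
50 mM sodium acetate pH 4.5 — the benchmark condition for this model.
They are convenient as worked-example inputs and as the parameter set the
validation suite exercises.
"""

from .budget import ProteinSpec
from .estimate import KineticParameters
from .simulate import CrystalHabit

#: Lysozyme crystal form: Matthews coefficient 1.84 Å³/Da, MW 14300 Da;
#: diffusion coefficient ≈0.5e-10 m²/s in the 15% PEG 4000 condition.
LYSOZYME = ProteinSpec(matthews_vm=1.84, mol_weight=14300.0, diffusion_coeff=0.5e-10)

#: Fitted kinetic constants for the benchmark condition:
#: C_e = 4.51 ± 5.78 mg/ml, A1 = 0.11 ± 0.05 µm·ml/(mg·h),
#: A2 = 8.47 ± 5.37, A3 = 1.49 ± 1.22.
LYSOZYME_PEG4000_PARAMS = KineticParameters(
    c_e=4.51, a1=0.11, a2=8.47, a3=1.49,
    c_e_se=5.78, a1_se=0.05, a2_se=5.37, a3_se=1.22,
)

#: Observed aspect ratios of the benchmark crystals (longest side = 1).
LYSOZYME_HABIT = CrystalHabit(a=1.0, b=0.84, c=0.77)

#: Protein density inside the lysozyme lattice, g/ml (from V_M = 1.84).
LYSOZYME_C_S = 0.901
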
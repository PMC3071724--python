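# Ten Tusscher-Noble-Noble-Panfilov (2004) human ventricular cell model:
# frozen parameter tables. Units: conductances nS/pF (G_CaL in cm^3 uF^-1 s^-1),
# concentrations mM, pump/exchanger maxima pA/pF, volumes um^3-scaled as in the
# published formulation, capacitance uF.

[physical]
R = 8314.472        # gas constant, J K^-1 kmol^-1
T = 310.0           # temperature, K
F = 96485.3415      # Faraday constant, C mol^-1
Cm = 0.185          # whole-cell capacitance used in concentration bookkeeping
V_c = 0.016404      # cytoplasmic volume
V_sr = 0.001094     # sarcoplasmic-reticulum volume

[extracellular]
Na_o = 140.0
K_o = 5.4
Ca_o = 2.0

[conductances]
G_Na = 14.838
G_CaL = 0.000175
G_Kr = 0.096
G_K1 = 5.405
G_pCa = 0.825
G_pK = 0.0146
G_bNa = 0.00029
G_bCa = 0.000592
P_NaK = 1.362
k_NaCa = 1000.0

# Layer-specific conductances: transient-outward and slow delayed-rectifier.
[conductances.by_cell_type.epi]
G_to = 0.294
G_Ks = 0.245

[conductances.by_cell_type.mid]
G_to = 0.294
G_Ks = 0.062

[conductances.by_cell_type.endo]
G_to = 0.073
G_Ks = 0.245

[exchanger]
gamma = 0.35
K_mCa = 1.38
K_mNai = 87.5
k_sat = 0.1
alpha = 2.5

[pump]
K_mK = 1.0
K_mNa = 40.0

[permeation]
p_KNa = 0.03
K_pCa = 0.0005

[sr_handling]
a_rel = 0.016464
b_rel = 0.25
c_rel = 0.008232
V_maxup = 0.000425
K_up = 0.00025
V_leak = 8.0e-5
tau_fCa = 2.0
tau_g = 2.0

[buffering]
Buf_c = 0.15
K_bufc = 0.001
Buf_sr = 10.0
K_bufsr = 0.3

# Published initial values (quiescent cell).
[initial_state]
V = -86.2
m = 0.0
h = 0.75
j = 0.75
d = 0.0
f = 1.0
f_Ca = 1.0
r = 0.0
s = 1.0
x_s = 0.0
x_r1 = 0.0
x_r2 = 1.0
g = 1.0
Na_i = 11.6
K_i = 138.3
Ca_i = 0.0002
Ca_SR = 0.2
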
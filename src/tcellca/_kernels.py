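"""Generated scalar kernels for the Ca2+ models.

Auto-generated by tools/generate_kernels.py from the symbolic model
definition; do not edit by hand. Each function takes the state
vector y and the parameter vector pv (ordering in PARAM_ORDER).
"""

import math

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional speed-up
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap

PARAM_ORDER = ('V_PLC', 'delta', 'gamma', 'V_PM', 'K_PM', 'V_SOCE', 's1', 'K_e', 'tau_s', 'V_SERCA', 'K_SERCA', 'K_bar', 'k_f', 'k_beta', 'K_p', 'K_c', 'K_h', 'tau_max', 'K_tau', 'tau_p', 'V_deg', 'K_deg', 'C_t')


@njit(cache=False)
def rhs_open(y, pv):
    c = y[0]
    c_e = y[1]
    h = y[2]
    p = y[3]
    s = y[4]
    V_PLC = pv[0]
    delta = pv[1]
    gamma = pv[2]
    V_PM = pv[3]
    K_PM = pv[4]
    V_SOCE = pv[5]
    s1 = pv[6]
    K_e = pv[7]
    tau_s = pv[8]
    V_SERCA = pv[9]
    K_SERCA = pv[10]
    K_bar = pv[11]
    k_f = pv[12]
    k_beta = pv[13]
    K_p = pv[14]
    K_c = pv[15]
    K_h = pv[16]
    tau_max = pv[17]
    K_tau = pv[18]
    tau_p = pv[19]
    V_deg = pv[20]
    K_deg = pv[21]
    C_t = pv[22]
    x0 = -s
    x1 = c**2
    x2 = 1/(K_SERCA**2 + x1)
    x3 = K_bar*c_e**2 - x1
    x4 = p**2
    x5 = c**4
    x6 = 1/(K_c**4 + x5)
    x7 = x5*x6
    x8 = h*x4*x7
    x9 = K_h**4
    x10 = x9/(x5 + x9)
    x11 = -c_e
    x12 = k_f*x8*(c + x11)/(k_beta*(-K_p**2*(x10*x7 - 1) + h*x4*x5*x6) + x8)
    x13 = K_tau**4
    out = np.empty(5)
    out[0] = V_SERCA*x2*x3 - delta*(V_PM*x1/(K_PM**2 + x1) + x0) - x12
    out[1] = -gamma*(V_SERCA*x2*x3 - x12)
    out[2] = (-h + x10)*(x13 + x5)/(tau_max*x13)
    out[3] = (V_PLC - V_deg*p*x1/(K_deg**2 + x1))/tau_p
    out[4] = (V_SOCE/(1 + math.exp(-s1*(K_e + x11))) + x0)/tau_s
    return out


@njit(cache=False)
def jac_open(y, pv):
    c = y[0]
    c_e = y[1]
    h = y[2]
    p = y[3]
    s = y[4]
    V_PLC = pv[0]
    delta = pv[1]
    gamma = pv[2]
    V_PM = pv[3]
    K_PM = pv[4]
    V_SOCE = pv[5]
    s1 = pv[6]
    K_e = pv[7]
    tau_s = pv[8]
    V_SERCA = pv[9]
    K_SERCA = pv[10]
    K_bar = pv[11]
    k_f = pv[12]
    k_beta = pv[13]
    K_p = pv[14]
    K_c = pv[15]
    K_h = pv[16]
    tau_max = pv[17]
    K_tau = pv[18]
    tau_p = pv[19]
    V_deg = pv[20]
    K_deg = pv[21]
    C_t = pv[22]
    x0 = c**2
    x1 = 1/(K_PM**2 + x0)
    x2 = p**2
    x3 = h*x2
    x4 = c**4
    x5 = K_c**4 + x4
    x6 = 1/x5
    x7 = x4*x6
    x8 = x3*x7
    x9 = -x8
    x10 = K_p**2
    x11 = K_h**4
    x12 = x11 + x4
    x13 = 1/x12
    x14 = x11*x13
    x15 = x14*x7 - 1
    x16 = x10*x15 + x9
    x17 = -k_beta*x16 + x8
    x18 = 1/x17
    x19 = k_f*x18
    x20 = x19*x3
    x21 = c**3
    x22 = x21*x6
    x23 = c**6
    x24 = -c_e
    x25 = c + x24
    x26 = x5**(-2)
    x27 = 4*x25
    x28 = x0*x6
    x29 = x3 + x9
    x30 = k_beta*(x10*x14*(x13*x4 + x7 - 1) + x29) + x29
    x31 = K_SERCA**2 + x0
    x32 = 2*V_SERCA
    x33 = x32/x31
    x34 = x33 + x32*(K_bar*c_e**2 - x0)/x31**2
    x35 = K_bar*c_e*x33
    x36 = -k_beta*x16 + x8
    x37 = 1/x36
    x38 = x37*x8
    x39 = k_beta + 1
    x40 = x2*x37
    x41 = k_f*x25
    x42 = x41*x7
    x43 = 1/(x10 + x2)
    x44 = h*x7
    x45 = x43*x8
    x46 = -x44 + x45
    x47 = -x10*x15*x43 + x46
    x48 = x2*x43 - 1
    x49 = 2*p
    x50 = x44*x49
    x51 = k_f*x3
    x52 = x37*x51
    x53 = x23*x26
    x54 = x27*x52
    x55 = x18*x2
    x56 = K_tau**4
    x57 = x4 + x56
    x58 = 1/(tau_max*x56)
    x59 = 1/(K_deg**2 + x0)
    x60 = x0*x59
    x61 = V_deg/tau_p
    x62 = 1/tau_s
    x63 = math.exp(-s1*(K_e + x24))
    out = np.empty(25)
    out[0] = c*(2*V_PM*delta*x1*(x0*x1 - 1) + 4*h*k_f*x18*x2*x23*x25*x26 + 4*h*k_f*x2*x23*x25*x26*x30/x17**2 - x20*x22 - x20*x27*x28 - x34)
    out[1] = k_f*x38 + x35
    out[2] = x40*x42*(x38*x39 - 1)
    out[3] = x37*x41*x50*(x40*(-k_beta*x47 - x46) + x48)
    out[4] = delta
    out[5] = c*gamma*(x22*x52 - x27*x30*x51*x53/x36**2 + x28*x54 + x34 - x53*x54)
    out[6] = -gamma*(x19*x8 + x35)
    out[7] = -gamma*x42*x55*(x18*x39*x8 - 1)
    out[8] = -gamma*x19*x25*x50*(x48 + x55*(-k_beta*x47 + x44 - x45))
    out[9] = 0
    out[10] = 4*x21*x58*(-h + x11*x13 - x11*x57/x12**2)
    out[11] = 0
    out[12] = -x57*x58
    out[13] = 0
    out[14] = 0
    out[15] = c*x49*x59*x61*(x60 - 1)
    out[16] = 0
    out[17] = 0
    out[18] = -x60*x61
    out[19] = 0
    out[20] = 0
    out[21] = -V_SOCE*s1*x62*x63/(x63 + 1)**2
    out[22] = 0
    out[23] = 0
    out[24] = -x62
    return out.reshape(5, 5)


@njit(cache=False)
def dpar_open(y, pv):
    c = y[0]
    c_e = y[1]
    h = y[2]
    p = y[3]
    s = y[4]
    V_PLC = pv[0]
    delta = pv[1]
    gamma = pv[2]
    V_PM = pv[3]
    K_PM = pv[4]
    V_SOCE = pv[5]
    s1 = pv[6]
    K_e = pv[7]
    tau_s = pv[8]
    V_SERCA = pv[9]
    K_SERCA = pv[10]
    K_bar = pv[11]
    k_f = pv[12]
    k_beta = pv[13]
    K_p = pv[14]
    K_c = pv[15]
    K_h = pv[16]
    tau_max = pv[17]
    K_tau = pv[18]
    tau_p = pv[19]
    V_deg = pv[20]
    K_deg = pv[21]
    C_t = pv[22]
    x0 = -s
    x1 = c**2
    x2 = K_PM**2 + x1
    x3 = x1/x2
    x4 = 2*x1
    x5 = K_SERCA**2 + x1
    x6 = 1/x5
    x7 = c_e**2
    x8 = K_bar*x7 - x1
    x9 = x6*x8
    x10 = 2*K_SERCA*V_SERCA*x8/x5**2
    x11 = V_SERCA*x6*x7
    x12 = p**2
    x13 = h*x12
    x14 = c**4
    x15 = K_c**4 + x14
    x16 = 1/x15
    x17 = x14*x16
    x18 = x13*x17
    x19 = K_p**2
    x20 = K_h**4
    x21 = 1/(x14 + x20)
    x22 = x20*x21
    x23 = x17*x22 - 1
    x24 = -x18 + x19*x23
    x25 = -k_beta*x24 + x18
    x26 = -c_e
    x27 = c + x26
    x28 = x18*x27
    x29 = x28/x25
    x30 = -x24
    x31 = x25**(-2)
    x32 = k_f*x28
    x33 = x30*x31*x32
    x34 = 1/(x12 + x19)
    x35 = 1/(k_beta*x30 + x18)
    x36 = x18*x34
    x37 = 2*K_p*x32*x35*(x34 - x35*(k_beta*(-x19*x23*x34 + x23 + x36) + x36))
    x38 = 4*k_f*x13*x27/x15**2
    x39 = K_c**3*x14*x35*x38*(-x17*x35*(-k_beta*(-x13 + x19*x22) + x13) + 1)
    x40 = K_h**3*x21*(x22 - 1)
    x41 = c**8*k_beta*x19*x31*x38*x40
    x42 = K_tau**4
    x43 = (x14 + x42)/x42
    x44 = 4/tau_max
    x45 = -h + x22
    x46 = 1/tau_p
    x47 = K_deg**2 + x1
    x48 = p*x1/x47
    x49 = 1/tau_s
    x50 = K_e + x26
    x51 = math.exp(-s1*x50)
    x52 = x51 + 1
    x53 = 1/x52
    x54 = V_SOCE*x49*x51/x52**2
    out = np.empty(115)
    out[0] = 0
    out[1] = -V_PM*x3 - x0
    out[2] = 0
    out[3] = -delta*x3
    out[4] = K_PM*V_PM*delta*x4/x2**2
    out[5] = 0
    out[6] = 0
    out[7] = 0
    out[8] = 0
    out[9] = x9
    out[10] = -x10
    out[11] = x11
    out[12] = -x29
    out[13] = x33
    out[14] = x37
    out[15] = x39
    out[16] = x41
    out[17] = 0
    out[18] = 0
    out[19] = 0
    out[20] = 0
    out[21] = 0
    out[22] = 0
    out[23] = 0
    out[24] = 0
    out[25] = -V_SERCA*x9 + h*k_f*x12*x14*x16*x27*x35
    out[26] = 0
    out[27] = 0
    out[28] = 0
    out[29] = 0
    out[30] = 0
    out[31] = 0
    out[32] = -gamma*x9
    out[33] = gamma*x10
    out[34] = -gamma*x11
    out[35] = gamma*x29
    out[36] = -gamma*x33
    out[37] = -gamma*x37
    out[38] = -gamma*x39
    out[39] = -gamma*x41
    out[40] = 0
    out[41] = 0
    out[42] = 0
    out[43] = 0
    out[44] = 0
    out[45] = 0
    out[46] = 0
    out[47] = 0
    out[48] = 0
    out[49] = 0
    out[50] = 0
    out[51] = 0
    out[52] = 0
    out[53] = 0
    out[54] = 0
    out[55] = 0
    out[56] = 0
    out[57] = 0
    out[58] = 0
    out[59] = 0
    out[60] = 0
    out[61] = 0
    out[62] = -x40*x43*x44
    out[63] = -x43*x45/tau_max**2
    out[64] = x44*x45*(1 - x43)/K_tau
    out[65] = 0
    out[66] = 0
    out[67] = 0
    out[68] = 0
    out[69] = x46
    out[70] = 0
    out[71] = 0
    out[72] = 0
    out[73] = 0
    out[74] = 0
    out[75] = 0
    out[76] = 0
    out[77] = 0
    out[78] = 0
    out[79] = 0
    out[80] = 0
    out[81] = 0
    out[82] = 0
    out[83] = 0
    out[84] = 0
    out[85] = 0
    out[86] = 0
    out[87] = 0
    out[88] = -(V_PLC - V_deg*x48)/tau_p**2
    out[89] = -x46*x48
    out[90] = K_deg*V_deg*p*x4*x46/x47**2
    out[91] = 0
    out[92] = 0
    out[93] = 0
    out[94] = 0
    out[95] = 0
    out[96] = 0
    out[97] = x49*x53
    out[98] = x50*x54
    out[99] = s1*x54
    out[100] = -(V_SOCE*x53 + x0)/tau_s**2
    out[101] = 0
    out[102] = 0
    out[103] = 0
    out[104] = 0
    out[105] = 0
    out[106] = 0
    out[107] = 0
    out[108] = 0
    out[109] = 0
    out[110] = 0
    out[111] = 0
    out[112] = 0
    out[113] = 0
    out[114] = 0
    return out.reshape(5, 23)


@njit(cache=False)
def rhs_closed(y, pv):
    c = y[0]
    h = y[1]
    p = y[2]
    V_PLC = pv[0]
    delta = pv[1]
    gamma = pv[2]
    V_PM = pv[3]
    K_PM = pv[4]
    V_SOCE = pv[5]
    s1 = pv[6]
    K_e = pv[7]
    tau_s = pv[8]
    V_SERCA = pv[9]
    K_SERCA = pv[10]
    K_bar = pv[11]
    k_f = pv[12]
    k_beta = pv[13]
    K_p = pv[14]
    K_c = pv[15]
    K_h = pv[16]
    tau_max = pv[17]
    K_tau = pv[18]
    tau_p = pv[19]
    V_deg = pv[20]
    K_deg = pv[21]
    C_t = pv[22]
    x0 = c**2
    x1 = C_t - c
    x2 = p**2
    x3 = c**4
    x4 = 1/(K_c**4 + x3)
    x5 = x3*x4
    x6 = h*x2*x5
    x7 = K_h**4
    x8 = x7/(x3 + x7)
    x9 = K_tau**4
    out = np.empty(3)
    out[0] = V_SERCA*(K_bar*gamma**2*x1**2 - x0)/(K_SERCA**2 + x0) - k_f*x6*(c - gamma*x1)/(k_beta*(-K_p**2*(x5*x8 - 1) + h*x2*x3*x4) + x6)
    out[1] = (-h + x8)*(x3 + x9)/(tau_max*x9)
    out[2] = (V_PLC - V_deg*p*x0/(K_deg**2 + x0))/tau_p
    return out


@njit(cache=False)
def jac_closed(y, pv):
    c = y[0]
    h = y[1]
    p = y[2]
    V_PLC = pv[0]
    delta = pv[1]
    gamma = pv[2]
    V_PM = pv[3]
    K_PM = pv[4]
    V_SOCE = pv[5]
    s1 = pv[6]
    K_e = pv[7]
    tau_s = pv[8]
    V_SERCA = pv[9]
    K_SERCA = pv[10]
    K_bar = pv[11]
    k_f = pv[12]
    k_beta = pv[13]
    K_p = pv[14]
    K_c = pv[15]
    K_h = pv[16]
    tau_max = pv[17]
    K_tau = pv[18]
    tau_p = pv[19]
    V_deg = pv[20]
    K_deg = pv[21]
    C_t = pv[22]
    x0 = c**2
    x1 = K_SERCA**2 + x0
    x2 = -c
    x3 = C_t + x2
    x4 = K_bar*gamma**2
    x5 = p**2
    x6 = h*x5
    x7 = c**4
    x8 = K_c**4 + x7
    x9 = 1/x8
    x10 = x7*x9
    x11 = x10*x6
    x12 = -x11
    x13 = K_p**2
    x14 = K_h**4
    x15 = x14 + x7
    x16 = 1/x15
    x17 = x14*x16
    x18 = x10*x17 - 1
    x19 = x12 + x13*x18
    x20 = -k_beta*x19 + x11
    x21 = 1/x20
    x22 = k_f*x21
    x23 = 4*c**3
    x24 = c - gamma*x3
    x25 = c**7
    x26 = x8**(-2)
    x27 = x12 + x6
    x28 = 1/(-k_beta*x19 + x11)
    x29 = x28*x5
    x30 = k_f*x24
    x31 = 1/(x13 + x5)
    x32 = h*x10
    x33 = x11*x31 - x32
    x34 = 2*p
    x35 = K_tau**4
    x36 = x35 + x7
    x37 = 1/(tau_max*x35)
    x38 = 1/(K_deg**2 + x0)
    x39 = x0*x38
    x40 = V_deg/tau_p
    out = np.empty(9)
    out[0] = -2*V_SERCA*c*(-x0 + x3**2*x4)/x1**2 + 2*V_SERCA*(x2 - x3*x4)/x1 + 4*h*k_f*x21*x24*x25*x26*x5 + 4*h*k_f*x24*x25*x26*x5*(k_beta*(x13*x17*(x10 + x16*x7 - 1) + x27) + x27)/x20**2 - x11*x22*(gamma + 1) - x22*x23*x24*x6*x9
    out[1] = x10*x29*x30*(x11*x28*(k_beta + 1) - 1)
    out[2] = x28*x30*x32*x34*(x29*(-k_beta*(-x13*x18*x31 + x33) - x33) + x31*x5 - 1)
    out[3] = x23*x37*(-h + x14*x16 - x14*x36/x15**2)
    out[4] = -x36*x37
    out[5] = 0
    out[6] = c*x34*x38*x40*(x39 - 1)
    out[7] = 0
    out[8] = -x39*x40
    return out.reshape(3, 3)


@njit(cache=False)
def dpar_closed(y, pv):
    c = y[0]
    h = y[1]
    p = y[2]
    V_PLC = pv[0]
    delta = pv[1]
    gamma = pv[2]
    V_PM = pv[3]
    K_PM = pv[4]
    V_SOCE = pv[5]
    s1 = pv[6]
    K_e = pv[7]
    tau_s = pv[8]
    V_SERCA = pv[9]
    K_SERCA = pv[10]
    K_bar = pv[11]
    k_f = pv[12]
    k_beta = pv[13]
    K_p = pv[14]
    K_c = pv[15]
    K_h = pv[16]
    tau_max = pv[17]
    K_tau = pv[18]
    tau_p = pv[19]
    V_deg = pv[20]
    K_deg = pv[21]
    C_t = pv[22]
    x0 = C_t - c
    x1 = gamma*x0
    x2 = c**2
    x3 = K_SERCA**2 + x2
    x4 = 1/x3
    x5 = V_SERCA*x4
    x6 = p**2
    x7 = h*x6
    x8 = c**4
    x9 = K_c**4 + x8
    x10 = x8/x9
    x11 = x10*x7
    x12 = K_p**2
    x13 = K_h**4
    x14 = 1/(x13 + x8)
    x15 = x13*x14
    x16 = x10*x15 - 1
    x17 = -x11 + x12*x16
    x18 = -k_beta*x17 + x11
    x19 = x11/x18
    x20 = 2*K_bar*x1*x5 + k_f*x19
    x21 = gamma**2*x0**2
    x22 = K_bar*x21 - x2
    x23 = c - x1
    x24 = -x17
    x25 = x18**(-2)
    x26 = k_f*x23
    x27 = x11*x26
    x28 = 1/(k_beta*x24 + x11)
    x29 = 1/(x12 + x6)
    x30 = x11*x29
    x31 = 4*x26*x7/x9**2
    x32 = K_h**3*x14*(x15 - 1)
    x33 = K_tau**4
    x34 = (x33 + x8)/x33
    x35 = 4/tau_max
    x36 = -h + x15
    x37 = 1/tau_p
    x38 = K_deg**2 + x2
    x39 = p*x2/x38
    out = np.empty(69)
    out[0] = 0
    out[1] = 0
    out[2] = x0*x20
    out[3] = 0
    out[4] = 0
    out[5] = 0
    out[6] = 0
    out[7] = 0
    out[8] = 0
    out[9] = x22*x4
    out[10] = -2*K_SERCA*V_SERCA*x22/x3**2
    out[11] = x21*x5
    out[12] = -x19*x23
    out[13] = x24*x25*x27
    out[14] = 2*K_p*x27*x28*(-x28*(k_beta*(-x12*x16*x29 + x16 + x30) + x30) + x29)
    out[15] = K_c**3*x28*x31*x8*(-x10*x28*(-k_beta*(x12*x15 - x7) + x7) + 1)
    out[16] = c**8*k_beta*x12*x25*x31*x32
    out[17] = 0
    out[18] = 0
    out[19] = 0
    out[20] = 0
    out[21] = 0
    out[22] = gamma*x20
    out[23] = 0
    out[24] = 0
    out[25] = 0
    out[26] = 0
    out[27] = 0
    out[28] = 0
    out[29] = 0
    out[30] = 0
    out[31] = 0
    out[32] = 0
    out[33] = 0
    out[34] = 0
    out[35] = 0
    out[36] = 0
    out[37] = 0
    out[38] = 0
    out[39] = -x32*x34*x35
    out[40] = -x34*x36/tau_max**2
    out[41] = x35*x36*(1 - x34)/K_tau
    out[42] = 0
    out[43] = 0
    out[44] = 0
    out[45] = 0
    out[46] = x37
    out[47] = 0
    out[48] = 0
    out[49] = 0
    out[50] = 0
    out[51] = 0
    out[52] = 0
    out[53] = 0
    out[54] = 0
    out[55] = 0
    out[56] = 0
    out[57] = 0
    out[58] = 0
    out[59] = 0
    out[60] = 0
    out[61] = 0
    out[62] = 0
    out[63] = 0
    out[64] = 0
    out[65] = -(V_PLC - V_deg*x39)/tau_p**2
    out[66] = -x37*x39
    out[67] = 2*K_deg*V_deg*p*x2*x37/x38**2
    out[68] = 0
    return out.reshape(3, 23)


@njit(cache=False)
def rhs_var_open(z, pv, ip):
    n = 5
    x = z[:n]
    f = rhs_open(x, pv)
    J = jac_open(x, pv)
    out = np.empty(z.size)
    out[:n] = f
    Phi = np.ascontiguousarray(z[n:n + n * n]).reshape(n, n)
    out[n:n + n * n] = (J @ Phi).ravel()
    if z.size > n + n * n:
        dp = dpar_open(x, pv)
        out[n + n * n:] = J @ z[n + n * n:] + dp[:, ip]
    return out


@njit(cache=False)
def rhs_var_closed(z, pv, ip):
    n = 3
    x = z[:n]
    f = rhs_closed(x, pv)
    J = jac_closed(x, pv)
    out = np.empty(z.size)
    out[:n] = f
    Phi = np.ascontiguousarray(z[n:n + n * n]).reshape(n, n)
    out[n:n + n * n] = (J @ Phi).ravel()
    if z.size > n + n * n:
        dp = dpar_closed(x, pv)
        out[n + n * n:] = J @ z[n + n * n:] + dp[:, ip]
    return out

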
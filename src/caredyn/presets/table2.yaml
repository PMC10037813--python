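# South Australian tertiary-level CAMHS (children and adolescents, 0-17y)
# case-study configuration.  The engagement rate i, progression rate v and
# the initial stocks are estimated from prevalence data and therefore unset
# here; u models ageing out of the 0-17 cohort (1/18 per year) and the
# spontaneous recovery rate is taken as zero.
i: null
gamma: 0.03468
v: null
u: 0.05556       # ageing outflow 1/18; spontaneous recovery assumed 0
k: 1.9423
theta: 9.3923
r: 0.6029
mu: 0.0004225
eta: 1.2190
g: 1823.6364
h: 970.2012
M0: null
S0: null
P0: 364622.2364
C0: 68773.7817
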
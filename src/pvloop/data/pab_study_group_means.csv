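# Baseline group means (SD) of the chronic pulmonary-artery-banding study
# emulated by pvloop.sim: control n=6, PAB n=5.  Units per variable name:
# pressures mmHg, volumes ml, CI L/min/m2, SVi ml/m2, resistance indices
# dyn.s/cm5, elastances and ESPVR/EDPVR slopes mmHg/ml, PRSW mmHg.ml/ml,
# dPdt mmHg/s, tau ms, EF %, HR 1/min, weight kg, BSA m2, lactate mM,
# NT_proBNP pg/ml.
variable,control_mean,control_sd,pab_mean,pab_sd
weight,37.7,0.9,37.8,4.5
BSA,0.8,0.01,0.8,0.06
HR,81.8,11.3,71.2,7.9
CI,5.3,1.1,4.1,0.5
SVi,64.6,6.8,57.5,2.2
SAP,90.2,1.7,78,6
DAP,58,9,52,7
MAP,71.8,9,63.8,7.8
SVRI,1226,355,1423,97
PVRI,140,81,358,99
RV_Ea,0.58,0.09,1.36,0.4
LV_Ea,1.76,0.28,2.09,0.82
RV_Pmax,27.4,1.9,44.7,9.7
LV_Pmax,84,5.6,68,4.8
RV_Pmean,15.1,1.0,23.2,5.1
LV_Pmean,39.9,5.0,42.7,5.3
RV_Pmin,7.1,1.1,6.6,3.1
LV_Pmin,7.6,1.8,7.6,1.4
RV_ESV,36.6,6.9,32.7,18
LV_ESV,40.2,6.7,12.7,8.1
RV_EDV,65.3,19.8,77.2,10.1
LV_EDV,82.3,7.9,55,4.9
RV_PRSW,10,3.5,15.2,5.2
LV_PRSW,44,8.8,41.8,17.9
RV_ESPVR,0.35,0.12,1.07,0.4
LV_ESPVR,0.9,0.08,1.32,0.5
RV_ESPVR_V0,-31.8,30.4,2.4,11.7
LV_ESPVR_V0,-38.3,16.9,-42.6,18.3
RV_dPdt_max,387.2,93.6,542.8,52.7
LV_dPdt_max,1081,240,1385,322
RV_Ea_over_ESPVR,1.88,0.8,1.34,0.3
LV_Ea_over_ESPVR,1.78,0.43,1.8,0.57
RV_EF,52.6,6.6,52.8,14
LV_EF,56,5,71,12
RV_dPdt_min,-378.5,95,-677.5,164.5
LV_dPdt_min,-1680,121,-1395,324
RV_tau,75.4,13.8,76.8,17
LV_tau,47,5.3,62,13.4
RV_EDPVR,0.16,0.04,0.15,0.05
LV_EDPVR,0.18,0.06,0.23,0.05
lactate,1.0,0.3,1.7,0.3
NT_proBNP,6.3,7.0,19.3,8.9
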
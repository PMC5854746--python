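# Per-patient long-term trough summary of the monitored study cohort
# (printed study data): arithmetic mean +- SD and range of weekly trough
# concentrations (ug/ml) under 100 mg erlotinib q.d.; ara_flag marks
# patients with acid-reducing co-medication.
patient,weeks_start,weeks_end,n,mean,sd,min,max,ara_flag
Pat.1,1,15,10,1.67,0.44,0.77,2.20,False
Pat.2,1,9,9,0.16,0.04,0.12,0.23,True
Pat.3,1,50,50,0.89,0.68,0.09,2.68,False
Pat.4,1,8,7,0.66,0.27,0.14,1.06,False
Pat.5,1,4,4,0.37,0.09,0.25,0.46,True
Pat.6,1,8,8,1.78,0.74,0.73,3.06,False
Pat.7,1,9,9,1.20,0.51,0.31,1.80,False
Pat.8,1,16,16,0.27,0.38,0.02,1.31,True
Pat.9,1,50,47,0.06,0.04,0.01,0.16,True
Pat.10,1,11,11,0.16,0.06,0.07,0.31,True
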
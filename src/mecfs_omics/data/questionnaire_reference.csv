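instrument,control_mean,control_sd,patient_mean,patient_sd
fsmc_total,22,2.4,74.8,15.5
fsmc_cognitive,11.8,2.1,37,8.9
fsmc_motor,10.3,0.5,37.8,7.2
sf36_physical_functioning,100,0,34,18.5
sf36_role_physical,100,0,5,11.2
sf36_role_emotional,100,0,100,0
sf36_energy_fatigue,75,18,24,30.1
sf36_emotional_wellbeing,93,6,62,26
sf36_social_functioning,97,6,35,32.4
sf36_pain,91,12,45,20.2
sf36_general_health,85,23,25,17.7
sf36_health_change,50,0,55,20.9
compass31_weighted,1.6,1.3,35.5,20.6
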
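# Across-animal mean +/- SD of MAP (mmHg) and tissue oxygenation index (%) at each
# vasoactive infusion dose, by volume condition and site, from a published swine
# stepwise-infusion experiment (n = 10 animals; lumbar site n = 9 after one loss).
# These five-point dose-response envelopes drive the worked regression example and
# serve as default MAP targets for the simulator.
condition,drug,dose_ug_kg_min,variable,mean,sd,n_animals
baseline,phenylephrine,0,map_mmHg,60,3,10
baseline,phenylephrine,0.5,map_mmHg,64,3,10
baseline,phenylephrine,1,map_mmHg,69,4,10
baseline,phenylephrine,2,map_mmHg,80,7,10
baseline,phenylephrine,5,map_mmHg,109,14,10
baseline,phenylephrine,0,toi_cerebral_pct,64.9,2.6,10
baseline,phenylephrine,0.5,toi_cerebral_pct,64.5,2.9,10
baseline,phenylephrine,1,toi_cerebral_pct,64.2,4.0,10
baseline,phenylephrine,2,toi_cerebral_pct,63.4,4.3,10
baseline,phenylephrine,5,toi_cerebral_pct,62.5,4.3,10
baseline,phenylephrine,0,toi_thoracic_pct,47.7,3.7,10
baseline,phenylephrine,0.5,toi_thoracic_pct,47.6,3.8,10
baseline,phenylephrine,1,toi_thoracic_pct,47.6,3.7,10
baseline,phenylephrine,2,toi_thoracic_pct,48.4,3.8,10
baseline,phenylephrine,5,toi_thoracic_pct,49.2,3.7,10
baseline,phenylephrine,0,toi_lumbar_pct,52.8,2.8,9
baseline,phenylephrine,0.5,toi_lumbar_pct,53.3,2.7,9
baseline,phenylephrine,1,toi_lumbar_pct,53.9,3.3,9
baseline,phenylephrine,2,toi_lumbar_pct,54.6,3.9,9
baseline,phenylephrine,5,toi_lumbar_pct,54.9,4.6,9
baseline,SNP,0,map_mmHg,69,8,10
baseline,SNP,0.5,map_mmHg,59,7,10
baseline,SNP,1,map_mmHg,54,6,10
baseline,SNP,2,map_mmHg,49,7,10
baseline,SNP,5,map_mmHg,41,7,10
baseline,SNP,0,toi_cerebral_pct,63.9,3.4,10
baseline,SNP,0.5,toi_cerebral_pct,63.2,2.8,10
baseline,SNP,1,toi_cerebral_pct,63.1,2.4,10
baseline,SNP,2,toi_cerebral_pct,62.4,2.2,10
baseline,SNP,5,toi_cerebral_pct,60.8,2.6,10
baseline,SNP,0,toi_thoracic_pct,47.2,3.7,10
baseline,SNP,0.5,toi_thoracic_pct,45.7,3.2,10
baseline,SNP,1,toi_thoracic_pct,45.1,2.9,10
baseline,SNP,2,toi_thoracic_pct,43.9,2.9,10
baseline,SNP,5,toi_thoracic_pct,41.8,3.1,10
baseline,SNP,0,toi_lumbar_pct,53.2,4.0,9
baseline,SNP,0.5,toi_lumbar_pct,51.8,3.7,9
baseline,SNP,1,toi_lumbar_pct,51.6,4.3,9
baseline,SNP,2,toi_lumbar_pct,50.4,4.3,9
baseline,SNP,5,toi_lumbar_pct,47.7,4.0,9
hypovolemia,phenylephrine,0,map_mmHg,48,8,10
hypovolemia,phenylephrine,0.5,map_mmHg,53,7,10
hypovolemia,phenylephrine,1,map_mmHg,56,6,10
hypovolemia,phenylephrine,2,map_mmHg,60,8,10
hypovolemia,phenylephrine,5,map_mmHg,80,11,10
hypovolemia,phenylephrine,0,toi_cerebral_pct,61.2,3.1,10
hypovolemia,phenylephrine,0.5,toi_cerebral_pct,61.4,2.8,10
hypovolemia,phenylephrine,1,toi_cerebral_pct,61.2,2.8,10
hypovolemia,phenylephrine,2,toi_cerebral_pct,60.3,2.3,10
hypovolemia,phenylephrine,5,toi_cerebral_pct,60.2,2.3,10
hypovolemia,phenylephrine,0,toi_thoracic_pct,42.2,4.7,10
hypovolemia,phenylephrine,0.5,toi_thoracic_pct,43.4,4.5,10
hypovolemia,phenylephrine,1,toi_thoracic_pct,44.4,3.9,10
hypovolemia,phenylephrine,2,toi_thoracic_pct,45.1,3.4,10
hypovolemia,phenylephrine,5,toi_thoracic_pct,46.5,3.6,10
hypovolemia,phenylephrine,0,toi_lumbar_pct,46.2,3.6,9
hypovolemia,phenylephrine,0.5,toi_lumbar_pct,47.6,3.8,9
hypovolemia,phenylephrine,1,toi_lumbar_pct,49.0,4.3,9
hypovolemia,phenylephrine,2,toi_lumbar_pct,49.7,4.4,9
hypovolemia,phenylephrine,5,toi_lumbar_pct,51.1,4.8,9
fluid_resuscitation,phenylephrine,0,map_mmHg,60,7,10
fluid_resuscitation,phenylephrine,0.5,map_mmHg,61,6,10
fluid_resuscitation,phenylephrine,1,map_mmHg,64,8,10
fluid_resuscitation,phenylephrine,2,map_mmHg,75,10,10
fluid_resuscitation,phenylephrine,5,map_mmHg,102,21,10
fluid_resuscitation,phenylephrine,0,toi_cerebral_pct,61.0,3.5,10
fluid_resuscitation,phenylephrine,0.5,toi_cerebral_pct,60.8,3.1,10
fluid_resuscitation,phenylephrine,1,toi_cerebral_pct,60.6,2.9,10
fluid_resuscitation,phenylephrine,2,toi_cerebral_pct,60.3,2.2,10
fluid_resuscitation,phenylephrine,5,toi_cerebral_pct,59.4,2.0,10
fluid_resuscitation,phenylephrine,0,toi_thoracic_pct,45.7,4.2,10
fluid_resuscitation,phenylephrine,0.5,toi_thoracic_pct,45.1,3.9,10
fluid_resuscitation,phenylephrine,1,toi_thoracic_pct,45.1,3.5,10
fluid_resuscitation,phenylephrine,2,toi_thoracic_pct,45.9,3.5,10
fluid_resuscitation,phenylephrine,5,toi_thoracic_pct,46.2,3.8,10
fluid_resuscitation,phenylephrine,0,toi_lumbar_pct,50.1,4.3,9
fluid_resuscitation,phenylephrine,0.5,toi_lumbar_pct,49.4,4.0,9
fluid_resuscitation,phenylephrine,1,toi_lumbar_pct,49.4,3.8,9
fluid_resuscitation,phenylephrine,2,toi_lumbar_pct,50.3,4.5,9
fluid_resuscitation,phenylephrine,5,toi_lumbar_pct,50.7,5.1,9
fluid_resuscitation,SNP,0,map_mmHg,56,7,10
fluid_resuscitation,SNP,0.5,map_mmHg,48,5,10
fluid_resuscitation,SNP,1,map_mmHg,44,5,10
fluid_resuscitation,SNP,2,map_mmHg,39,5,10
fluid_resuscitation,SNP,5,map_mmHg,34,3,10
fluid_resuscitation,SNP,0,toi_cerebral_pct,60.2,3.0,10
fluid_resuscitation,SNP,0.5,toi_cerebral_pct,59.0,2.4,10
fluid_resuscitation,SNP,1,toi_cerebral_pct,58.8,3.2,10
fluid_resuscitation,SNP,2,toi_cerebral_pct,57.5,2.6,10
fluid_resuscitation,SNP,5,toi_cerebral_pct,54.7,3.0,10
fluid_resuscitation,SNP,0,toi_thoracic_pct,43.9,2.9,10
fluid_resuscitation,SNP,0.5,toi_thoracic_pct,41.9,2.7,10
fluid_resuscitation,SNP,1,toi_thoracic_pct,41.6,2.5,10
fluid_resuscitation,SNP,2,toi_thoracic_pct,40.4,2.7,10
fluid_resuscitation,SNP,5,toi_thoracic_pct,38.4,2.6,10
fluid_resuscitation,SNP,0,toi_lumbar_pct,48.1,4.0,9
fluid_resuscitation,SNP,0.5,toi_lumbar_pct,46.0,3.9,9
fluid_resuscitation,SNP,1,toi_lumbar_pct,45.7,4.8,9
fluid_resuscitation,SNP,2,toi_lumbar_pct,44.2,4.6,9
fluid_resuscitation,SNP,5,toi_lumbar_pct,41.1,3.2,9
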
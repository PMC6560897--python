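tissue	group
heart_atrium	heart
heart_ventricle	heart
cerebral_cortex	brain
cerebellum	brain
amygdala	brain
cingulate_cortex	brain
nucleus_accumbens	brain
subthalamic_nucleus	brain
liver	other
blood	other
lung	other
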
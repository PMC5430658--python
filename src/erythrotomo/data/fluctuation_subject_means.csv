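subject,group,hba1c_rank,sigma_nm
h1,healthy,1,59.7
h2,healthy,2,58.3
h3,healthy,3,55.0
h4,healthy,4,57.1
h5,healthy,5,51.0
h6,healthy,6,49.6
d1,diabetic,1,45.1
d2,diabetic,2,46.9
d3,diabetic,3,48.8
d4,diabetic,4,47.6
d5,diabetic,5,43.0
d6,diabetic,6,48.0
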
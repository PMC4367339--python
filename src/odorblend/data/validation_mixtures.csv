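section,odorant_a,odorant_b,lnoav_a,lnoav_b,oi_a_m_printed,oi_b_m_printed,oi_pre_printed,oi_mea
A,PA,VA,2.18,0.56,1.32,-0.07,2.6,2.3
A,PA,VA,3.09,2.87,0.81,0.73,4.6,4.3
A,PA,VA,2.87,1.48,1.07,0.36,3.6,3.5
A,PA,HEP,0.57,1.95,0.00,1.21,2.4,2.3
A,PA,HEP,3.97,1.48,1.16,0.15,4.8,4.3
A,PA,HEP,2.87,1.48,1.07,0.36,3.6,3.8
A,VA,HEP,1.26,0.56,1.11,0.27,1.6,1.8
A,VA,HEP,2.87,3.27,0.70,0.84,4.7,4.8
A,VA,HEP,2.18,2.17,0.77,0.77,3.4,3.3
B,BA,HEX,2.16,0.78,1.16,0.14,2.6,2.7
B,BA,HEX,2.85,2.68,0.80,0.74,4.3,4.2
B,BA,HEX,2.16,4.29,0.35,1.07,5.4,4.8
B,BA,HEP,0.77,1.63,0.31,1.09,2.0,2.2
B,BA,HEP,2.16,1.98,0.81,0.72,3.2,2.9
B,BA,HEP,3.95,1.76,1.11,0.27,4.9,5.2
B,IVA,VA,0.90,1.95,0.29,1.10,2.4,2.8
B,IVA,VA,2.18,2.17,0.77,0.77,3.4,3.8
B,IVA,VA,2.87,2.17,0.91,0.61,3.9,5.0
B,IVA,IBA,1.88,0.60,1.19,0.06,2.3,2.7
B,IVA,IBA,2.18,1.99,0.82,0.72,3.2,3.8
B,IVA,IBA,1.48,3.37,0.26,1.11,4.1,4.7
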
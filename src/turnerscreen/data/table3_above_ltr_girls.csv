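id,karyotype,age_years,ht_sds,ltr_sds,bw_sds,comment
T3-01,45X,1.78,-1.52,-2.45,-0.02,Father short (Ht SDS -2.09)
T3-02,45X,2.40,-1.42,-2.71,N/A,
T3-03,45X,2.46,-0.62,-1.25,0.09,
T3-04,45X_47XXX,2.51,-0.60,-1.88,N/A,
T3-05,45X,2.69,-0.57,-1.43,N/A,
T3-06,45X_47XXX,3.01,-0.75,-0.83,-2.74,
T3-07,45X,3.23,-1.25,-1.31,1.08,
T3-08,45X,3.27,-2.15,-2.78,1.98,Father short (Ht SDS -2.2)
T3-09,45X_47XXX,4.24,-1.19,-1.73,-1.76,
T3-10,45X,4.93,-2.15,-2.66,-1.30,
T3-11,45X_46XX,4.99,-0.32,-1.72,N/A,
T3-12,45X_46XrX,7.20,-1.05,-1.46,N/A,
T3-13,45X_46XX,9.08,-2.75,-2.85,N/A,
T3-14,45X,9.10,-2.02,-2.16,-1.34,
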
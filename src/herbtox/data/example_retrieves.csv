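query_id,cid,score,endpoint,verdict
3-hydroxystigmast-5-en-7-one,6010,0.992,Hepatotoxicity,0
3-hydroxystigmast-5-en-7-one,6010,0.992,Carcinogenicity,N.A.
3-hydroxystigmast-5-en-7-one,10631,0.986,Hepatotoxicity,0
3-hydroxystigmast-5-en-7-one,10631,0.986,Carcinogenicity,N.A.
3-hydroxystigmast-5-en-7-one,5997,0.976,Hepatotoxicity,N.A.
3-hydroxystigmast-5-en-7-one,5997,0.976,Carcinogenicity,-1
3-hydroxystigmast-5-en-7-one,6917715,0.917,Hepatotoxicity,0
3-hydroxystigmast-5-en-7-one,6917715,0.917,Carcinogenicity,N.A.
3-hydroxystigmast-5-en-7-one,54454,0.540,Hepatotoxicity,0
3-hydroxystigmast-5-en-7-one,54454,0.540,Carcinogenicity,N.A.
3-hydroxystigmast-5-en-7-one,53232,0.520,Hepatotoxicity,0
3-hydroxystigmast-5-en-7-one,53232,0.520,Carcinogenicity,N.A.
3-hydroxystigmast-5-en-7-one,5280453,0.498,Hepatotoxicity,-1
3-hydroxystigmast-5-en-7-one,5280453,0.498,Carcinogenicity,N.A.
3-hydroxystigmast-5-en-7-one,445354,0.302,Hepatotoxicity,1
3-hydroxystigmast-5-en-7-one,445354,0.302,Carcinogenicity,N.A.
beta-sitosterol,5997,0.999,Hepatotoxicity,N.A.
beta-sitosterol,5997,0.999,Carcinogenicity,-1
beta-sitosterol,5280453,0.804,Hepatotoxicity,-1
beta-sitosterol,5280453,0.804,Carcinogenicity,N.A.
beta-sitosterol,445354,0.588,Hepatotoxicity,1
beta-sitosterol,445354,0.588,Carcinogenicity,N.A.
beta-sitosterol,445354,0.588,Hepatotoxicity,1
beta-sitosterol,445354,0.588,Carcinogenicity,N.A.
campesterol,5997,0.999,Hepatotoxicity,N.A.
campesterol,5997,0.999,Carcinogenicity,-1
campesterol,5280453,0.836,Hepatotoxicity,-1
campesterol,5280453,0.836,Carcinogenicity,N.A.
campesterol,445354,0.594,Hepatotoxicity,1
campesterol,445354,0.594,Carcinogenicity,N.A.
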
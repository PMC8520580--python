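group,lower,upper
55 and above,443,450
55 and above,421,426
55 and above,436,450
55 and above,376,385
55 and above,458,458
55 and above,408,420
55 and above,422,425
55 and above,431,440
55 and above,459,462
55 and above,369,369
55 and above,360,360
55 and above,431,445
55 and above,403,415
55 and above,436,445
55 and above,376,376
55 and above,370,370
55 and above,443,443
55 and above,445,445
55 and above,355,365
55 and above,450,450
35-55,359,361
35-55,352,365
35-55,445,455
35-55,410,410
35-55,458,464
35-55,410,415
35-55,463,470
35-55,580,584
35-55,432,440
35-55,379,379
35-55,370,370
35-55,584,589
35-55,410,416
35-55,587,590
35-55,415,415
35-55,419,422
35-55,357,357
35-55,467,472
35-55,415,418
35-55,358,358
35 and below,460,465
35 and below,427,429
35 and below,407,410
35 and below,378,380
35 and below,364,368
35 and below,345,349
35 and below,342,346
35 and below,345,345
35 and below,313,318
35 and below,277,280
35 and below,268,271
35 and below,259,262
35 and below,256,260
35 and below,251,251
35 and below,249,249
35 and below,223,227
35 and below,209,211
35 and below,187,191
35 and below,173,175
35 and below,168,168
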
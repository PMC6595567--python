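<?xml version='1.0' encoding='UTF-8'?>
<!-- One study with two reports (many-to-one), all five characteristics
     fields, a risk-of-bias table, and one dichotomous outcome. -->
<COCHRANE_REVIEW ID="EX-SINGLE" REVMAN_VERSION="5.3">
  <COVER_SHEET><TITLE>Haloperidol versus placebo for schizophrenia</TITLE></COVER_SHEET>
  <STUDIES_AND_REFERENCES>
    <STUDIES>
      <INCLUDED_STUDIES>
        <STUDY ID="Smith 1999">
          <!-- first report: the study's primary publication -->
          <REFERENCE ID="EX-SINGLE-01-1">
            <TI>A randomised double-blind trial of haloperidol</TI>
            <SO>Journal of Clinical Psychiatry</SO>
            <YR>1999</YR>
          </REFERENCE>
          <!-- a second report of the same study, published later -->
          <REFERENCE ID="EX-SINGLE-01-2">
            <TI>Long-term follow-up of the haloperidol trial</TI>
            <YR>2001</YR>
          </REFERENCE>
        </STUDY>
      </INCLUDED_STUDIES>
    </STUDIES>
  </STUDIES_AND_REFERENCES>
  <CHARACTERISTICS_OF_STUDIES>
    <CHARACTERISTICS_OF_INCLUDED_STUDIES>
      <INCLUDED_CHAR STUDY_ID="Smith 1999">
        <CHAR_METHODS><P>Allocation: randomised. Blinding: double blind. Duration: 12 weeks.</P></CHAR_METHODS>
        <CHAR_PARTICIPANTS><P>N=120 inpatients with schizophrenia.</P></CHAR_PARTICIPANTS>
        <CHAR_INTERVENTIONS><P><B>Haloperidol</B> versus placebo.</P></CHAR_INTERVENTIONS>
        <CHAR_OUTCOMES><P>Clinical response, adverse effects.</P></CHAR_OUTCOMES>
        <CHAR_NOTES><P>Funding not stated.</P></CHAR_NOTES>
      </INCLUDED_CHAR>
    </CHARACTERISTICS_OF_INCLUDED_STUDIES>
  </CHARACTERISTICS_OF_STUDIES>
  <RISK_OF_BIAS>
    <ROB_TABLE STUDY_ID="Smith 1999">
      <ROB_ENTRY NAME="Random sequence generation" RESULT="LOW">Computer-generated list.</ROB_ENTRY>
      <ROB_ENTRY NAME="Allocation concealment" RESULT="UNCLEAR">Not described.</ROB_ENTRY>
    </ROB_TABLE>
  </RISK_OF_BIAS>
  <ANALYSES_AND_DATA>
    <COMPARISON ID="CMP-01">
      <NAME>HALOPERIDOL versus PLACEBO</NAME>
      <DICH_OUTCOME ID="OUT-01.01">
        <NAME>Mental state</NAME>
        <!-- events <= total per arm is an invariant -->
        <DICH_DATA STUDY_ID="Smith 1999" EVENTS_1="24" TOTAL_1="60" EVENTS_2="35" TOTAL_2="60"/>
      </DICH_OUTCOME>
    </COMPARISON>
  </ANALYSES_AND_DATA>
</COCHRANE_REVIEW>
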
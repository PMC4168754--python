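<?xml version='1.0' encoding='UTF-8'?>
<Pathway xmlns="http://pathvisio.org/GPML/2013a" Name="Synthetic pathway (seed 7)" Organism="Homo sapiens" Version="2013a">
  <Graphics BoardWidth="900.0" BoardHeight="600.0"/>
  <DataNode TextLabel="GENE0" GraphId="dn0" Type="GeneProduct">
    <Graphics CenterX="100.0" CenterY="100.0" Width="80.0" Height="20.0" FillColor="FFFFFF" ShapeType="Rectangle" Color="000000" ZOrder="0" LineThickness="1.0"/>
    <Xref Database="Entrez Gene" ID="1000"/>
  </DataNode>
  <DataNode TextLabel="GENE1" GraphId="dn1" Type="GeneProduct">
    <Graphics CenterX="250.0" CenterY="100.0" Width="80.0" Height="20.0" FillColor="FFFFFF" ShapeType="Rectangle" Color="000000" ZOrder="0" LineThickness="1.0"/>
    <Xref Database="Entrez Gene" ID="1000"/>
  </DataNode>
  <DataNode TextLabel="GENE2" GraphId="dn2" Type="GeneProduct">
    <Graphics CenterX="400.0" CenterY="100.0" Width="80.0" Height="20.0" FillColor="FFFFFF" ShapeType="Rectangle" Color="000000" ZOrder="0" LineThickness="1.0"/>
    <Xref Database="Entrez Gene" ID="1001"/>
  </DataNode>
  <DataNode TextLabel="GENE3" GraphId="dn3" Type="GeneProduct" GroupRef="grp0">
    <Graphics CenterX="550.0" CenterY="100.0" Width="80.0" Height="20.0" FillColor="FFFFFF" ShapeType="Rectangle" Color="000000" ZOrder="0" LineThickness="1.0"/>
    <Xref Database="Entrez Gene" ID="1002"/>
  </DataNode>
  <DataNode TextLabel="GENE4" GraphId="dn4" Type="GeneProduct" GroupRef="grp0">
    <Graphics CenterX="700.0" CenterY="100.0" Width="80.0" Height="20.0" FillColor="FFFFFF" ShapeType="Rectangle" Color="000000" ZOrder="0" LineThickness="1.0"/>
    <Xref Database="Entrez Gene" ID="1003"/>
  </DataNode>
  <Interaction GraphId="ia0">
    <Graphics Color="000000" ZOrder="0" LineThickness="1.0">
      <Point X="400.0" Y="100.0" GraphRef="dn2"/>
      <Point X="250.0" Y="100.0" GraphRef="dn1" ArrowHead="Arrow"/>
      <Anchor Position="0.5" GraphId="anch0" Shape="None"/>
    </Graphics>
    <Xref Database="" ID=""/>
  </Interaction>
  <Interaction GraphId="ia1">
    <Graphics Color="000000" ZOrder="0" LineThickness="1.0">
      <Point X="550.0" Y="100.0" GraphRef="dn3"/>
      <Point X="100.0" Y="100.0" GraphRef="dn0" ArrowHead="Arrow"/>
    </Graphics>
    <Xref Database="" ID=""/>
  </Interaction>
  <Interaction GraphId="ia2">
    <Graphics Color="000000" ZOrder="0" LineThickness="1.0">
      <Point X="100.0" Y="100.0" GraphRef="dn0"/>
      <Point X="250.0" Y="100.0" GraphRef="dn1" ArrowHead="Arrow"/>
    </Graphics>
    <Xref Database="" ID=""/>
  </Interaction>
  <Label TextLabel="Region 0" GraphId="lab0">
    <Graphics CenterX="100.0" CenterY="200.0" Width="90.0" Height="16.0" FillColor="FFFFFF" ShapeType="Rectangle" Color="000000" ZOrder="0" LineThickness="1.0"/>
  </Label>
  <Shape GraphId="shp0">
    <Graphics CenterX="250.0" CenterY="200.0" Width="120.0" Height="80.0" FillColor="FFFFFF" ShapeType="Oval" Color="000000" ZOrder="0" LineThickness="1.0"/>
  </Shape>
  <Group GroupId="grp0" Style="Group" GraphId="g0"/>
</Pathway>
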